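"""Seeded forward simulator of a library-on-library yeast mating screen.

The physical model: MATa yeast display TCR variants, MATalpha yeast display
pMHC variants, and the two pools are mixed.  A pair's propensity to form a
diploid is ``e = base + (max - base) * strength`` where ``strength`` in
[0, 1] is the planted interaction strength of the (TCR group, pMHC variant)
pair — a linear map, the simplest monotone choice.  The diploid pool is a
multinomial draw over pairs with weights ``abundance_a * abundance_alpha *
e``, once per replicate at the configured read depth.  Amplicon reads are
then emitted for each diploid: either the variable payload behind its
conserved anchor (peptide / CDR3 screens) or the Cre-loxP-juxtaposed
barcode pair (library-on-library screens), with i.i.d. substitution errors.

Stop-codon variants cannot display a payload, so their interaction
strengths are forced to zero; they still mate at the background rate, which
is what makes them usable as internal normalization controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .screen_model import (
    AmpliconScheme,
    BARCODE_LEN,
    PREFERRED_CODON,
    ScreenDesign,
    StrainRecord,
    reverse_translate,
    write_strain_registry,
)

# Fixed spacer between the juxtaposed barcodes on a recombined amplicon.
BARCODE_SPACER = "ACCGGT"

_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class SimConfig:
    """Parameters of one simulated mating pot.

    ``a_abundances`` / ``alpha_abundances`` give haploid strain frequencies
    per mating type (each summing to 1).  ``interaction_strengths`` maps
    (MATa group, MATalpha strain) to a strength in [0, 1];
    pairs absent from the map have strength 0 (background mating only).
    Defaults: background diploid rate 5e-4, cognate-pair rate 2e-2,
    substitution error 1e-3 per base.
    """

    seed: int
    read_depth: int
    replicates: int
    a_abundances: dict[str, float]
    alpha_abundances: dict[str, float]
    interaction_strengths: dict[tuple[str, str], float] = field(default_factory=dict)
    a_groups: dict[str, str] | None = None  # strain -> group; identity if omitted
    base_mating_rate: float = 5e-4
    max_mating_rate: float = 0.02
    per_base_error: float = 1e-3

    def group_of(self, a_strain: str) -> str:
        return (self.a_groups or {}).get(a_strain, a_strain)

    def validate(self) -> None:
        if not self.a_abundances or not self.alpha_abundances:
            raise ValueError("abundance maps must be non-empty")
        for name, ab in (("MATa", self.a_abundances), ("MATalpha", self.alpha_abundances)):
            total = sum(ab.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} abundances sum to {total}, expected 1")
            if any(v < 0 for v in ab.values()):
                raise ValueError(f"{name} abundances must be >= 0")
        if not 0.0 <= self.base_mating_rate <= self.max_mating_rate <= 1.0:
            raise ValueError("need 0 <= base_mating_rate <= max_mating_rate <= 1")
        if any(not 0.0 <= s <= 1.0 for s in self.interaction_strengths.values()):
            raise ValueError("interaction strengths must be in [0, 1]")
        if not 0.0 <= self.per_base_error < 1.0:
            raise ValueError("per_base_error must be in [0, 1)")
        if self.read_depth < 0 or self.replicates < 1:
            raise ValueError("read_depth must be >= 0 and replicates >= 1")


@dataclass
class SimTruth:
    """Ground truth of one simulated pot.

    ``expected_diploid_fraction`` is the exact multinomial probability per
    (a_strain, alpha_strain) pair; ``replicate_counts`` the realized draws;
    ``planted_cognate_pairs`` the (a_group, alpha_strain) pairs with
    strength > 0.
    """

    expected_diploid_fraction: dict[tuple[str, str], float]
    planted_cognate_pairs: set[tuple[str, str]]
    replicate_counts: dict[str, dict[tuple[str, str], int]]

    @property
    def realized_diploid_counts(self) -> dict[tuple[str, str], int]:
        total: dict[tuple[str, str], int] = {}
        for counts in self.replicate_counts.values():
            for pair, n in counts.items():
                total[pair] = total.get(pair, 0) + n
        return total


def zero_stop_strengths(
    strengths: Mapping[tuple[str, str], float], registry: Sequence[StrainRecord]
) -> dict[tuple[str, str], float]:
    """Force interaction strength 0 for any pair touching a stop-codon strain."""
    stop_groups = {r.group_id for r in registry if r.is_internal_control}
    stop_strains = {r.strain_id for r in registry if r.is_internal_control}
    return {
        (g, v): s
        for (g, v), s in strengths.items()
        if g not in stop_groups and v not in stop_strains
    }


def simulate_mating(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    replicate_labels: Sequence[str] | None = None,
) -> SimTruth:
    """Draw the diploid composition of a mating pot, one multinomial per replicate."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    a_ids = list(config.a_abundances)
    alpha_ids = list(config.alpha_abundances)
    a_ab = np.array([config.a_abundances[s] for s in a_ids])
    al_ab = np.array([config.alpha_abundances[s] for s in alpha_ids])
    strength = np.zeros((len(a_ids), len(alpha_ids)))
    for i, a in enumerate(a_ids):
        g = config.group_of(a)
        for j, v in enumerate(alpha_ids):
            strength[i, j] = config.interaction_strengths.get((g, v), 0.0)
    rate = config.base_mating_rate + (config.max_mating_rate - config.base_mating_rate) * strength
    weight = np.outer(a_ab, al_ab) * rate
    total = weight.sum()
    if total <= 0:
        raise ValueError("all pair weights are zero; nothing can mate")
    prob = (weight / total).ravel()
    pairs = [(a, v) for a in a_ids for v in alpha_ids]
    if replicate_labels is None:
        replicate_labels = [f"rep{i + 1}" for i in range(config.replicates)]
    replicate_counts = {}
    for label in replicate_labels:
        draw = rng.multinomial(config.read_depth, prob)
        replicate_counts[label] = {p: int(n) for p, n in zip(pairs, draw)}
    planted = {
        (config.group_of(a), v)
        for (a, v), s in (
            ((a, v), config.interaction_strengths.get((config.group_of(a), v), 0.0))
            for a in a_ids
            for v in alpha_ids
        )
        if s > 0
    }
    return SimTruth(
        expected_diploid_fraction=dict(zip(pairs, prob)),
        planted_cognate_pairs=planted,
        replicate_counts=replicate_counts,
    )


# --- read emission -------------------------------------------------------

_BASE_LOOKUP = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _pair_core(
    a_rec: StrainRecord, alpha_rec: StrainRecord, scheme: AmpliconScheme
) -> str:
    """The invariant portion of a barcode-pair amplicon (both anchors + barcodes)."""
    core = (
        scheme.forward_anchor
        + a_rec.barcodes[0]
        + BARCODE_SPACER
        + _revcomp(alpha_rec.barcodes[0])
        + _revcomp(scheme.reverse_anchor)
    )
    # The 5'-most anchor occurrences must be the intended ones, or the exact
    # round-trip contract of noiseless simulation would silently break.
    if core.find(scheme.forward_anchor) != 0:
        raise ValueError("spurious forward anchor in barcode-pair core")
    rc = _revcomp(core)
    if rc.find(scheme.reverse_anchor) != 0:
        raise ValueError("spurious reverse anchor in barcode-pair core")
    return core


def _payload_cores(
    counts: Mapping[tuple[str, str], int],
    by_id: Mapping[str, StrainRecord],
    scheme: AmpliconScheme,
) -> list[tuple[str, int]]:
    """Collapse pair counts to (core sequence, count) for the scheme's read layout."""
    if scheme.mode == "barcode_pair":
        return [
            (_pair_core(by_id[a], by_id[v], scheme), n)
            for (a, v), n in counts.items()
            if n > 0
        ]
    side = 1 if scheme.mode == "peptide" else 0  # which parent is sequenced
    agg: dict[str, int] = {}
    for pair, n in counts.items():
        if n > 0:
            agg[pair[side]] = agg.get(pair[side], 0) + n
    return [(scheme.forward_anchor + by_id[sid].payload_dna, n) for sid, n in agg.items()]


_PAD_MAX = 8  # random 5' pad of 0..8 bp; anchors have no self-overlap border,
_TAIL_PAD = 4  # so pads cannot create a spurious 5'-most anchor match.


def _assemble_reads(
    cores: Sequence[tuple[str, int]], per_base_error: float, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Vectorized read assembly: [random pad][core][random tail] + substitution errors.

    Returns (array of n_reads byte strings, read length).
    """
    if not cores:
        return np.array([], dtype="S1"), 0
    core_len = len(cores[0][0])
    if any(len(c) != core_len for c, _ in cores):
        raise ValueError("all cores in one pot must share a length")
    length = _PAD_MAX + core_len + _TAIL_PAD
    n_reads = sum(n for _, n in cores)
    mat = rng.integers(0, 4, size=(n_reads, length), dtype=np.uint8)
    offsets = rng.integers(0, _PAD_MAX + 1, size=n_reads)
    span = np.arange(core_len)
    pos = 0
    for core, n in cores:
        code = _encode(core)
        offs = offsets[pos : pos + n]
        for off in np.unique(offs):
            rows = pos + np.nonzero(offs == off)[0]
            mat[rows[:, None], off + span] = code
        pos += n
    if per_base_error > 0:
        mask = rng.random(size=mat.shape) < per_base_error
        k = int(mask.sum())
        if k:
            mat[mask] = (mat[mask] + rng.integers(1, 4, size=k, dtype=np.uint8)) % 4
    mat = mat[rng.permutation(n_reads)]
    seqs = _BASE_LOOKUP[mat]
    return seqs.reshape(n_reads, length).view(f"S{length}").ravel(), length


def emit_amplicon_reads(
    truth: SimTruth,
    registry: Sequence[StrainRecord],
    scheme: AmpliconScheme,
    config: SimConfig,
    out_dir: str | Path,
    prefix: str = "sim",
    rng: np.random.Generator | None = None,
) -> dict[str, Path]:
    """Write one Phred+33 FASTQ per replicate; returns replicate -> path.

    Reads are ``[0-8 bp pad][anchor + payload][4 bp pad]`` in payload modes,
    or ``[pad][fwd anchor][a barcode][spacer][revcomp(alpha barcode)]
    [revcomp(rev anchor)][pad]`` in barcode-pair mode.  Qualities are a
    constant Q37 (base-call noise is modeled on the sequence, not the
    quality string).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if rng is None:
        rng = np.random.default_rng([config.seed, 0xE11])
    by_id = {r.strain_id: r for r in registry}
    for counts in truth.replicate_counts.values():
        for a, v in counts:
            if a not in by_id or v not in by_id:
                raise ValueError(f"simulated strain pair ({a!r}, {v!r}) missing from registry")
    paths = {}
    for rep, counts in truth.replicate_counts.items():
        cores = _payload_cores(counts, by_id, scheme)
        seqs, length = _assemble_reads(cores, config.per_base_error, rng)
        path = out_dir / f"{prefix}_{rep}.fastq"
        qual = b"F" * length  # Q37
        rep_b = rep.encode()
        with open(path, "wb") as fh:
            buf = bytearray()
            for i, s in enumerate(seqs):
                buf += b"@%s:%d\n%s\n+\n%s\n" % (rep_b, i, s, qual)
                if len(buf) > 8_000_000:
                    fh.write(buf)
                    buf = bytearray()
            fh.write(buf)
        paths[rep] = path
    return paths


# --- presets -------------------------------------------------------------

PRESETS = (
    "peptide_screen",
    "tcr_screen",
    "library_on_library",
    "dilution_1e2",
    "dilution_1e4",
)

SL9 = "SLYNTVATL"  # HIV-1 Gag index peptide
TAX = "LLFGYPVYV"  # HTLV-1 index peptide
QL9 = "QLSPFPFDL"  # murine H-2Ld index peptide (2C TCR ligand)

# VaCDR3 octamers for the TCR-library preset.  The wild-type spelling and the
# 12 unnamed single-substitution mutants are synthetic stand-ins (only three
# non-enriched mutants and the stop control are reported by name upstream).
CDR3_WT = "GAHDYALN"
CDR3_STOP = "GAHDY*LN"
CDR3_WEAK_MUTANTS = ("GLHDYALN", "GACDYALN", "LAHDYALN")  # bind weakly; not enriched
CDR3_STRONG_MUTANTS = (
    "SAHDYALN", "GTHDYALN", "GAHDFALN", "GAHEYALN", "GAHDYSLN", "GAHDYAIN",
    "GAHDYALQ", "GAHDWALN", "CAHDYALN", "GVHDYALN", "GAHDYTLN", "GAHDYALH",
)

_PEPTIDE_MUT_POS = 2  # third residue, 0-based

# Planted mating strengths for the SL9 position-3 peptide library.  Mating
# strength (agglutination) and T-cell activation are distinct axes: 3K mates
# but does not activate; 3I/3M/3V activate but mate too weakly (or are too
# rare) to enrich.
_PEPTIDE_STRENGTHS = {
    "SL9": 1.0, "3F": 0.9, "3L": 0.85, "3H": 0.8, "3W": 0.75, "3Q": 0.6, "3K": 0.55,
}

# T-cell activation fractions defining the ground truth (9 cognates above the
# 10% rule).  SL9's 75.6% is the reported activation of the index peptide;
# the rest are synthetic stand-ins consistent with the screen's outcome.
PEPTIDE_ACTIVATION = {
    "SL9": 0.756, "3F": 0.62, "3I": 0.65, "3L": 0.58, "3H": 0.55, "3W": 0.50,
    "3Q": 0.30, "3M": 0.16, "3V": 0.13,
    "3K": 0.05, "3A": 0.03, "3C": 0.02, "3D": 0.01, "3E": 0.02, "3G": 0.02,
    "3N": 0.03, "3P": 0.01, "3R": 0.04, "3S": 0.03, "3T": 0.02, "3*": 0.0,
}

_TCR_ACTIVATION = {CDR3_WT: 0.9, CDR3_STOP: 0.0}
_TCR_ACTIVATION.update({m: 0.35 for m in CDR3_WEAK_MUTANTS})  # tetramer-positive
_TCR_ACTIVATION.update({m: 0.6 for m in CDR3_STRONG_MUTANTS})

_PRESET_DEPTH = {
    "peptide_screen": 50_000,
    "tcr_screen": 50_000,
    "library_on_library": 50_000,
    "dilution_1e2": 100_000,
    "dilution_1e4": 1_000_000,
}
_PRESET_REPLICATES = {
    "peptide_screen": 4,
    "tcr_screen": 4,
    "library_on_library": 4,
    "dilution_1e2": 3,
    "dilution_1e4": 3,
}


def _random_barcode(rng: np.random.Generator, taken: set[str]) -> str:
    from .screen_model import BARCODE_FORWARD_ANCHOR, BARCODE_REVERSE_ANCHOR

    banned = (
        BARCODE_FORWARD_ANCHOR,
        BARCODE_REVERSE_ANCHOR,
        _revcomp(BARCODE_FORWARD_ANCHOR),
        _revcomp(BARCODE_REVERSE_ANCHOR),
    )
    while True:
        bc = "".join("ACGT"[i] for i in rng.integers(0, 4, size=BARCODE_LEN))
        if bc in taken or any(b in bc for b in banned):
            continue
        taken.add(bc)
        return bc


def _peptide_variants() -> dict[str, str]:
    """SL9 saturation set at the third residue: wild type, 19 substitutions, stop."""
    wt = SL9[_PEPTIDE_MUT_POS]
    variants = {"SL9": SL9}
    for aa in "ACDEFGHIKLMNPQRSTVW*":
        if aa == wt:
            continue
        name = f"3{aa}"
        variants[name] = SL9[:_PEPTIDE_MUT_POS] + aa + SL9[_PEPTIDE_MUT_POS + 1 :]
    return variants


def _make_records(
    specs: Iterable[tuple[str, str, str, str]], rng: np.random.Generator, taken: set[str]
) -> list[StrainRecord]:
    """specs: (strain_id, group_id, kind, amino-acid payload)."""
    records = []
    for sid, gid, kind, aa in specs:
        mt = "a" if kind == "TCR" else "alpha"
        records.append(
            StrainRecord(
                strain_id=sid,
                mating_type=mt,
                payload_kind=kind,
                payload_dna=reverse_translate(aa),
                group_id=gid,
                barcodes=(_random_barcode(rng, taken),),
            )
        )
    return records


@dataclass
class FixtureBundle:
    """Everything a screen run needs, written under ``out_dir``."""

    preset: str
    out_dir: Path
    registry: list[StrainRecord]
    design: ScreenDesign
    scheme: AmpliconScheme
    configs: dict[str, SimConfig]  # one per arm ("pooled" for single-pot modes)
    truths: dict[str, SimTruth]
    fastq: dict[str, Path]  # replicate label -> path
    replicate_arms: dict[str, str]  # replicate label -> "experimental" | "control"
    ground_truth: pd.DataFrame  # variant_id, activation_fraction
    registry_path: Path
    design_path: Path
    manifest_path: Path  # TSV: fastq, replicate, arm
    ground_truth_path: Path


def _arm_screen_fixture(
    preset: str,
    seed: int,
    out_dir: Path,
    depth: int,
    replicates: int,
    per_base_error: float,
) -> FixtureBundle:
    rng_bc = np.random.default_rng([seed, 0xBC])
    taken: set[str] = set()
    if preset == "peptide_screen":
        scheme = AmpliconScheme.peptide()
        variants = _peptide_variants()
        alpha_specs = [(name, name, "pMHC", aa) for name, aa in variants.items()]
        a_specs = [("868", "868", "TCR", CDR3_WT),
                   ("A6", "A6", "TCR", "GTHDYALN"),
                   ("2C", "2C", "TCR", "GAHDFALN")]
        registry = _make_records(a_specs + alpha_specs, rng_bc, taken)
        # Unequally distributed library: the index peptide, 3F and 3I are rare.
        rare = {"SL9": 0.01, "3F": 0.012, "3I": 0.008}
        rest = [v for v in variants if v not in rare]
        remaining = 1.0 - sum(rare.values())
        mixing = dict(rare)
        mixing.update({v: remaining / len(rest) for v in rest})
        strengths = {("868", v): s for v, s in _PEPTIDE_STRENGTHS.items()}
        design = ScreenDesign(
            experimental_groups=["868"],
            control_groups=["A6", "2C"],
            internal_control="3*",
            replicates=replicates,
            mixing_proportions=mixing,
        )
        arm_a = {"experimental": {"868": 1.0}, "control": {"A6": 0.5, "2C": 0.5}}
        alpha_ab = mixing
        activation = dict(PEPTIDE_ACTIVATION)
    elif preset == "tcr_screen":
        scheme = AmpliconScheme.cdr3()
        cdr3s = [CDR3_WT, *CDR3_STRONG_MUTANTS, *CDR3_WEAK_MUTANTS, CDR3_STOP]
        a_specs = [(c, c, "TCR", c) for c in cdr3s]
        alpha_specs = [("SL9", "SL9", "pMHC", SL9),
                       ("TAX", "TAX", "pMHC", TAX),
                       ("3*", "3*", "pMHC", SL9[:2] + "*" + SL9[3:])]
        registry = _make_records(a_specs + alpha_specs, rng_bc, taken)
        mixing = {c: 1.0 / len(cdr3s) for c in cdr3s}
        strengths = {(CDR3_WT, "SL9"): 1.0}
        strengths.update({(m, "SL9"): 0.7 for m in CDR3_STRONG_MUTANTS})
        design = ScreenDesign(
            experimental_groups=["SL9"],
            control_groups=["TAX", "3*"],
            internal_control=CDR3_STOP,
            replicates=replicates,
            mixing_proportions=mixing,
        )
        # Arms are on the pMHC side here; the sequenced axis is the TCR library.
        arm_a = {"experimental": None, "control": None}
        alpha_ab = None
        activation = dict(_TCR_ACTIVATION)
    else:  # pragma: no cover
        raise ValueError(preset)

    write_paths: dict[str, Path] = {}
    truths: dict[str, SimTruth] = {}
    configs: dict[str, SimConfig] = {}
    replicate_arms: dict[str, str] = {}
    ss = np.random.SeedSequence(seed)
    arm_seeds = {arm: int(s.generate_state(1)[0] % 2**31)
                 for arm, s in zip(("experimental", "control"), ss.spawn(2))}
    for arm in ("experimental", "control"):
        if preset == "peptide_screen":
            a_ab, al_ab = arm_a[arm], alpha_ab
        else:  # tcr_screen: library on the MATa side, arm strain(s) on MATalpha
            a_ab = mixing
            groups = design.experimental_groups if arm == "experimental" else design.control_groups
            al_ab = {g: 1.0 / len(groups) for g in groups}
        cfg = SimConfig(
            seed=arm_seeds[arm],
            read_depth=depth,
            replicates=replicates,
            a_abundances=a_ab,
            alpha_abundances=al_ab,
            interaction_strengths=zero_stop_strengths(strengths, registry),
            per_base_error=per_base_error,
        )
        labels = [f"{arm}_rep{i + 1}" for i in range(replicates)]
        truth = simulate_mating(cfg, replicate_labels=labels)
        paths = emit_amplicon_reads(truth, registry, scheme, cfg, out_dir / "fastq")
        configs[arm] = cfg
        truths[arm] = truth
        write_paths.update(paths)
        replicate_arms.update({lab: arm for lab in labels})

    ground_truth = pd.DataFrame(
        sorted(activation.items()), columns=["variant_id", "activation_fraction"]
    )
    return _finalize_bundle(
        preset, out_dir, registry, design, scheme, configs, truths,
        write_paths, replicate_arms, ground_truth,
    )


def _pooled_fixture(
    preset: str,
    seed: int,
    out_dir: Path,
    depth: int,
    replicates: int,
    per_base_error: float,
) -> FixtureBundle:
    rng_bc = np.random.default_rng([seed, 0xBC])
    taken: set[str] = set()
    scheme = AmpliconScheme.barcode_pair()
    tax8 = TAX[:7] + "*" + TAX[8:]
    sl9_3star = SL9[:2] + "*" + SL9[3:]
    alpha_specs = [
        ("SL9", "SL9", "pMHC", SL9),
        ("3L", "3L", "pMHC", SL9[:2] + "L" + SL9[3:]),
        ("TAX", "TAX", "pMHC", TAX),
        ("3*", "3*", "pMHC", sl9_3star),
        ("TAX8*", "TAX8*", "pMHC", tax8),
    ]
    # Two independently barcoded clones per TCR group.
    a_specs = [
        (f"{g}-{i}", g, "TCR", c)
        for g, c in (("868", CDR3_WT), ("A6", "GTHDYALN"), ("2C", "GAHDFALN"))
        for i in (1, 2)
    ]
    registry = _make_records(a_specs + alpha_specs, rng_bc, taken)
    strengths = {("868", "SL9"): 1.0, ("868", "3L"): 0.7}
    a_ab = {r.strain_id: 1.0 / 6 for r in registry if r.payload_kind == "TCR"}
    a_groups = {r.strain_id: r.group_id for r in registry if r.payload_kind == "TCR"}
    if preset == "library_on_library":
        alpha_ab = {v: 0.2 for v, *_ in alpha_specs}
        control = "TAX8*"
    else:
        dilution = 1e-2 if preset == "dilution_1e2" else 1e-4
        # SL9, 3L and TAX8* are spiked in at `dilution` relative to each of
        # the abundant negatives (3* and TAX).
        y = 1.0 / (2.0 + 3.0 * dilution)
        alpha_ab = {"3*": y, "TAX": y, "SL9": y * dilution, "3L": y * dilution,
                    "TAX8*": y * dilution}
        control = "3*"
    design = ScreenDesign(
        experimental_groups=["868"],
        control_groups=["A6", "2C"],
        internal_control=control,
        replicates=replicates,
        mixing_proportions=alpha_ab,
    )
    cfg = SimConfig(
        seed=int(np.random.SeedSequence(seed).generate_state(1)[0] % 2**31),
        read_depth=depth,
        replicates=replicates,
        a_abundances=a_ab,
        alpha_abundances=alpha_ab,
        interaction_strengths=zero_stop_strengths(strengths, registry),
        a_groups=a_groups,
        per_base_error=per_base_error,
    )
    labels = [f"rep{i + 1}" for i in range(replicates)]
    truth = simulate_mating(cfg, replicate_labels=labels)
    paths = emit_amplicon_reads(truth, registry, scheme, cfg, out_dir / "fastq")
    replicate_arms = {lab: "pooled" for lab in labels}
    activation = {"SL9": 0.756, "3L": 0.58, "TAX": 0.02, "3*": 0.0, "TAX8*": 0.0}
    ground_truth = pd.DataFrame(
        sorted(activation.items()), columns=["variant_id", "activation_fraction"]
    )
    return _finalize_bundle(
        preset, out_dir, registry, design, scheme, {"pooled": cfg}, {"pooled": truth},
        paths, replicate_arms, ground_truth,
    )


def _finalize_bundle(
    preset, out_dir, registry, design, scheme, configs, truths, fastq,
    replicate_arms, ground_truth,
) -> FixtureBundle:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    registry_path = out_dir / "registry.tsv"
    write_strain_registry(registry, registry_path)
    design_path = out_dir / "design.yaml"
    design.save(design_path)
    gt_path = out_dir / "ground_truth.tsv"
    ground_truth.to_csv(gt_path, sep="\t", index=False)
    manifest_path = out_dir / "manifest.tsv"
    # Paths are stored relative to the manifest so a bundle is relocatable
    # and two same-seed runs are byte-identical wherever they land.
    rows = [
        {
            "fastq": str(Path(fastq[rep]).relative_to(out_dir)),
            "replicate": rep,
            "arm": replicate_arms[rep],
        }
        for rep in sorted(fastq)
    ]
    pd.DataFrame(rows, columns=["fastq", "replicate", "arm"]).to_csv(
        manifest_path, sep="\t", index=False
    )
    # Truth tables, for inspection and round-trip tests.
    truth_rows = []
    for arm, truth in truths.items():
        for (a, v), frac in sorted(truth.expected_diploid_fraction.items()):
            row = {"arm": arm, "a_strain": a, "alpha_strain": v, "expected_fraction": frac}
            for rep, counts in truth.replicate_counts.items():
                row[rep] = counts[(a, v)]
            truth_rows.append(row)
    pd.DataFrame(truth_rows).to_csv(out_dir / "sim_truth.tsv", sep="\t", index=False)
    return FixtureBundle(
        preset=preset,
        out_dir=out_dir,
        registry=registry,
        design=design,
        scheme=scheme,
        configs=configs,
        truths=truths,
        fastq=fastq,
        replicate_arms=replicate_arms,
        ground_truth=ground_truth,
        registry_path=registry_path,
        design_path=design_path,
        manifest_path=manifest_path,
        ground_truth_path=gt_path,
    )


def generate_screen_fixture(
    preset: str,
    seed: int,
    out_dir: str | Path,
    read_depth: int | None = None,
    replicates: int | None = None,
    per_base_error: float | None = None,
) -> FixtureBundle:
    """Generate a self-contained simulated screen under ``out_dir``.

    Presets: ``peptide_screen`` (SL9 position-3 library vs the 868 TCR, A6/2C
    controls), ``tcr_screen`` (VaCDR3 library vs SL9, TAX/3* controls),
    ``library_on_library`` (equal five-peptide mix, barcode-pair readout),
    ``dilution_1e2`` / ``dilution_1e4`` (cognate peptides spiked 10^2- or
    10^4-fold below the negatives).  Deterministic given (preset, seed).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; valid presets: {', '.join(PRESETS)}")
    depth = read_depth if read_depth is not None else _PRESET_DEPTH[preset]
    reps = replicates if replicates is not None else _PRESET_REPLICATES[preset]
    err = per_base_error if per_base_error is not None else 1e-3
    out_dir = Path(out_dir)
    if preset in ("peptide_screen", "tcr_screen"):
        return _arm_screen_fixture(preset, seed, out_dir, depth, reps, err)
    return _pooled_fixture(preset, seed, out_dir, depth, reps, err)


__all__ = [
    "BARCODE_SPACER",
    "CDR3_STOP",
    "CDR3_STRONG_MUTANTS",
    "CDR3_WEAK_MUTANTS",
    "CDR3_WT",
    "FixtureBundle",
    "PEPTIDE_ACTIVATION",
    "PRESETS",
    "QL9",
    "SL9",
    "SimConfig",
    "SimTruth",
    "TAX",
    "emit_amplicon_reads",
    "generate_screen_fixture",
    "simulate_mating",
    "zero_stop_strengths",
]
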