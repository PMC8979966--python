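"""Domain model for mating-based TCR-pMHC interaction screens.

A screen mixes MATa yeast displaying single-chain TCRs with MATalpha yeast
displaying peptide-MHC (pMHC) complexes; diploid formation is promoted by
TCR-pMHC binding, so sequencing the diploid pool reads out interactions.
This module holds the shared vocabulary: strain records (one displayed
variant with its coding DNA and identifying barcodes), amplicon schemes
(the anchor sequences used to locate payloads in reads), the screen design
(experimental vs control arms, internal stop-codon control, cutoffs), plus
codon machinery for NNK saturation-mutagenesis libraries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio.Seq import Seq

# Conserved amplicon anchors flanking the variable payloads.  Payload
# extraction requires an exact match of these strings.
PEPTIDE_ANCHOR = "GTTTTTCAATATTTTCTGTTATTGCTAGCGTTTTAGCA"  # 38 bp, 5' of peptide
CDR3_ANCHOR = "GATTCTGCTACTTATTTGTGTGCTGTTAGA"  # 30 bp, 5' of VaCDR3
BARCODE_FORWARD_ANCHOR = "GAAAAGCGGC"  # 10 bp, 5' of the MATa barcode
BARCODE_REVERSE_ANCHOR = "CCAGGTATCG"  # 10 bp, 5' of the MATalpha barcode (on the reverse strand)

PEPTIDE_PAYLOAD_LEN = 27  # 9-mer peptide
CDR3_PAYLOAD_LEN = 24  # 8-mer CDR3
BARCODE_LEN = 15

_DNA_ALPHABET = frozenset("ACGT")

_ROLE_PAYLOAD_LEN = {"pMHC": PEPTIDE_PAYLOAD_LEN, "TCR": CDR3_PAYLOAD_LEN}
_ROLE_MATING_TYPE = {"TCR": "a", "pMHC": "alpha"}

# One representative (yeast-common) codon per amino acid, used when a fixture
# needs a coding sequence for a stated peptide.  '*' maps to TAG, the single
# stop codon reachable by an NNK codon.
PREFERRED_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTG",
    "M": "ATG", "N": "AAT", "P": "CCA", "Q": "CAA", "R": "AGA",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
    "*": "TAG",
}

NNK_CODONS = tuple(a + b + c for a in "ACGT" for b in "ACGT" for c in "GT")


def check_dna(seq: str, what: str = "sequence") -> None:
    """Raise ValueError unless *seq* is non-empty uppercase ACGT."""
    if not seq or (set(seq) - _DNA_ALPHABET):
        raise ValueError(f"{what} must be non-empty uppercase ACGT, got {seq!r}")


def translate_codons(dna: str) -> str:
    """Translate an in-frame coding sequence with the standard code.

    Stop codons are rendered ``'*'``.  Raises ValueError for non-ACGT
    characters or a length that is not a multiple of 3.
    """
    check_dna(dna, "coding sequence")
    if len(dna) % 3:
        raise ValueError(f"coding sequence length {len(dna)} is not a multiple of 3")
    return str(Seq(dna).translate())


def reverse_translate(aa: str) -> str:
    """Back-translate an amino-acid string with one fixed codon per residue."""
    try:
        return "".join(PREFERRED_CODON[a] for a in aa)
    except KeyError as exc:
        raise ValueError(f"cannot reverse-translate residue {exc.args[0]!r}") from None


def nnk_enumerate(position_count: int = 1) -> list[str]:
    """Enumerate all NNK codon combinations for *position_count* positions.

    One NNK position (N = A/C/G/T, K = G/T) yields 32 codons covering the 20
    amino acids plus the single stop TAG; k positions yield the 32**k
    Cartesian product, each entry a 3k bp string.
    """
    if position_count < 1:
        raise ValueError("position_count must be >= 1")
    return ["".join(p) for p in itertools.product(NNK_CODONS, repeat=position_count)]


def estimate_library_diversity(clone_count: int, insertion_efficiency: float) -> float:
    """Library diversity estimate: clones after limiting dilution x correct-insertion rate."""
    if clone_count < 0:
        raise ValueError("clone_count must be >= 0")
    if not 0.0 <= insertion_efficiency <= 1.0:
        raise ValueError("insertion_efficiency must be in [0, 1]")
    return clone_count * insertion_efficiency


@dataclass(frozen=True)
class StrainRecord:
    """One displayed variant (a TCR or a pMHC) and its identifying barcodes.

    ``group_id`` joins strains sharing a biological identity (e.g. two
    independently barcoded clones of the same TCR).  ``is_internal_control``
    marks premature-stop variants, which cannot display a functional payload
    and serve as the normalization denominator.
    """

    strain_id: str
    mating_type: str  # "a" (TCR side) or "alpha" (pMHC side)
    payload_kind: str  # "TCR" or "pMHC"
    payload_dna: str
    group_id: str
    barcodes: tuple[str, ...]
    payload_aa: str = field(default="", compare=False)
    is_internal_control: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.payload_kind not in _ROLE_PAYLOAD_LEN:
            raise ValueError(f"unknown payload_kind {self.payload_kind!r}")
        expected_mt = _ROLE_MATING_TYPE[self.payload_kind]
        if self.mating_type != expected_mt:
            raise ValueError(
                f"strain {self.strain_id!r}: payload_kind {self.payload_kind} "
                f"requires mating_type {expected_mt!r}, got {self.mating_type!r}"
            )
        expected_len = _ROLE_PAYLOAD_LEN[self.payload_kind]
        check_dna(self.payload_dna, f"strain {self.strain_id!r} payload_dna")
        if len(self.payload_dna) != expected_len:
            raise ValueError(
                f"strain {self.strain_id!r}: {self.payload_kind} payload must be "
                f"{expected_len} bp, got {len(self.payload_dna)}"
            )
        if not self.barcodes:
            raise ValueError(f"strain {self.strain_id!r} has no barcode")
        for bc in self.barcodes:
            check_dna(bc, f"strain {self.strain_id!r} barcode")
            if len(bc) != BARCODE_LEN:
                raise ValueError(
                    f"strain {self.strain_id!r}: barcode must be {BARCODE_LEN} bp, got {len(bc)}"
                )
        aa = translate_codons(self.payload_dna)
        object.__setattr__(self, "payload_aa", aa)
        object.__setattr__(self, "is_internal_control", "*" in aa)


_REGISTRY_COLUMNS = ["strain_id", "mating_type", "role", "group_id", "payload_dna", "barcode"]


def load_strain_registry(path: str | Path) -> list[StrainRecord]:
    """Load a strain registry TSV (one row per strain x barcode).

    Rows sharing a ``strain_id`` accumulate barcodes and must agree on every
    other field.  Raises ValueError on malformed DNA, payload-length
    mismatch, inconsistent duplicate strain rows, or a barcode claimed by
    more than one strain.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_REGISTRY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"registry {path} lacks columns: {sorted(missing)}")
    rows: dict[str, dict] = {}
    barcode_owner: dict[str, str] = {}
    for _, row in df.iterrows():
        sid = row["strain_id"]
        bc = row["barcode"]
        if bc in barcode_owner:
            raise ValueError(
                f"duplicate barcode {bc!r}: owned by {barcode_owner[bc]!r} and {sid!r}"
            )
        barcode_owner[bc] = sid
        attrs = (row["mating_type"], row["role"], row["group_id"], row["payload_dna"])
        if sid in rows:
            if rows[sid]["attrs"] != attrs:
                raise ValueError(f"conflicting rows for duplicate strain_id {sid!r}")
            rows[sid]["barcodes"].append(bc)
        else:
            rows[sid] = {"attrs": attrs, "barcodes": [bc]}
    records = []
    for sid, entry in rows.items():
        mt, role, gid, dna = entry["attrs"]
        records.append(
            StrainRecord(
                strain_id=sid,
                mating_type=mt,
                payload_kind=role,
                payload_dna=dna,
                group_id=gid,
                barcodes=tuple(entry["barcodes"]),
            )
        )
    return records


def write_strain_registry(records: Iterable[StrainRecord], path: str | Path) -> None:
    """Write records as a TSV, one row per (strain, barcode)."""
    rows = [
        {
            "strain_id": r.strain_id,
            "mating_type": r.mating_type,
            "role": r.payload_kind,
            "group_id": r.group_id,
            "payload_dna": r.payload_dna,
            "barcode": bc,
        }
        for r in records
        for bc in r.barcodes
    ]
    pd.DataFrame(rows, columns=_REGISTRY_COLUMNS).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class AmpliconScheme:
    """How to locate payloads in an amplicon read.

    ``peptide`` and ``cdr3`` modes extract a fixed-length payload immediately
    after an exact match of the forward anchor.  ``barcode_pair`` mode
    extracts the MATa barcode after the forward anchor on the read and the
    MATalpha barcode after the reverse anchor on the reverse-complemented
    read (the two barcodes are juxtaposed on one amplicon by Cre-loxP
    recombination in the diploid).
    """

    mode: str  # "peptide" | "cdr3" | "barcode_pair"
    forward_anchor: str
    payload_len: int
    reverse_anchor: str | None = None
    reverse_payload_len: int | None = None
    orientation_policy: str = "also_revcomp"  # or "as_is"

    def __post_init__(self) -> None:
        if self.orientation_policy not in ("as_is", "also_revcomp"):
            raise ValueError(f"unknown orientation_policy {self.orientation_policy!r}")
        check_dna(self.forward_anchor, "forward_anchor")
        if self.mode == "peptide":
            if len(self.forward_anchor) != 38 or self.payload_len != PEPTIDE_PAYLOAD_LEN:
                raise ValueError("peptide mode requires a 38 bp anchor and 27 bp payload")
        elif self.mode == "cdr3":
            if len(self.forward_anchor) != 30 or self.payload_len != CDR3_PAYLOAD_LEN:
                raise ValueError("cdr3 mode requires a 30 bp anchor and 24 bp payload")
        elif self.mode == "barcode_pair":
            if self.reverse_anchor is None or self.reverse_payload_len is None:
                raise ValueError("barcode_pair mode requires both anchors")
            check_dna(self.reverse_anchor, "reverse_anchor")
            if (
                len(self.forward_anchor) != 10
                or len(self.reverse_anchor) != 10
                or self.payload_len != BARCODE_LEN
                or self.reverse_payload_len != BARCODE_LEN
            ):
                raise ValueError(
                    "barcode_pair mode requires 10 bp anchors and 15 bp payloads"
                )
        else:
            raise ValueError(f"unknown scheme mode {self.mode!r}")

    @classmethod
    def peptide(cls, orientation_policy: str = "also_revcomp") -> "AmpliconScheme":
        return cls("peptide", PEPTIDE_ANCHOR, PEPTIDE_PAYLOAD_LEN,
                   orientation_policy=orientation_policy)

    @classmethod
    def cdr3(cls, orientation_policy: str = "also_revcomp") -> "AmpliconScheme":
        return cls("cdr3", CDR3_ANCHOR, CDR3_PAYLOAD_LEN,
                   orientation_policy=orientation_policy)

    @classmethod
    def barcode_pair(cls, orientation_policy: str = "also_revcomp") -> "AmpliconScheme":
        return cls(
            "barcode_pair",
            BARCODE_FORWARD_ANCHOR,
            BARCODE_LEN,
            reverse_anchor=BARCODE_REVERSE_ANCHOR,
            reverse_payload_len=BARCODE_LEN,
            orientation_policy=orientation_policy,
        )

    @classmethod
    def for_mode(cls, mode: str) -> "AmpliconScheme":
        try:
            return {"peptide": cls.peptide, "cdr3": cls.cdr3,
                    "barcode_pair": cls.barcode_pair}[mode]()
        except KeyError:
            raise ValueError(f"unknown scheme mode {mode!r}") from None


@dataclass
class ScreenDesign:
    """Arms, internal control and cutoffs for one screen.

    ``experimental_groups`` / ``control_groups`` name the mating-partner
    groups that define the experimental and control arms (TCR groups in a
    peptide screen, pMHC strains in a CDR3 screen, TCR groups in
    library-on-library mode).  ``internal_control`` is the stop-codon
    variant used as the normalization denominator on the sequenced axis.
    """

    experimental_groups: list[str]
    control_groups: list[str]
    internal_control: str
    replicates: int = 3
    fold_change_cutoff: float = 1.0
    p_cutoff: float = 0.05
    activation_threshold: float = 0.10
    mixing_proportions: dict[str, float] | None = None

    def validate(self, registry: Sequence[StrainRecord] | None = None) -> None:
        overlap = set(self.experimental_groups) & set(self.control_groups)
        if overlap:
            raise ValueError(f"experimental and control groups overlap: {sorted(overlap)}")
        if not self.experimental_groups or not self.control_groups:
            raise ValueError("both experimental and control groups are required")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.mixing_proportions is not None:
            total = sum(self.mixing_proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mixing_proportions sum to {total}, expected 1")
        if registry is not None:
            by_id = {r.strain_id: r for r in registry}
            rec = by_id.get(self.internal_control)
            if rec is None:
                raise ValueError(f"internal control {self.internal_control!r} not in registry")
            if not rec.is_internal_control:
                raise ValueError(
                    f"internal control {self.internal_control!r} carries no stop codon"
                )

    def to_dict(self) -> dict:
        d = {
            "experimental_groups": list(self.experimental_groups),
            "control_groups": list(self.control_groups),
            "internal_control": self.internal_control,
            "replicates": self.replicates,
            "fold_change_cutoff": self.fold_change_cutoff,
            "p_cutoff": self.p_cutoff,
            "activation_threshold": self.activation_threshold,
        }
        if self.mixing_proportions is not None:
            d["mixing_proportions"] = dict(self.mixing_proportions)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScreenDesign":
        return cls(
            experimental_groups=list(d["experimental_groups"]),
            control_groups=list(d["control_groups"]),
            internal_control=d["internal_control"],
            replicates=int(d.get("replicates", 3)),
            fold_change_cutoff=float(d.get("fold_change_cutoff", 1.0)),
            p_cutoff=float(d.get("p_cutoff", 0.05)),
            activation_threshold=float(d.get("activation_threshold", 0.10)),
            mixing_proportions=(
                dict(d["mixing_proportions"]) if d.get("mixing_proportions") else None
            ),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "ScreenDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


__all__ = [
    "AmpliconScheme",
    "BARCODE_FORWARD_ANCHOR",
    "BARCODE_LEN",
    "BARCODE_REVERSE_ANCHOR",
    "CDR3_ANCHOR",
    "CDR3_PAYLOAD_LEN",
    "NNK_CODONS",
    "PEPTIDE_ANCHOR",
    "PEPTIDE_PAYLOAD_LEN",
    "PREFERRED_CODON",
    "ScreenDesign",
    "StrainRecord",
    "check_dna",
    "estimate_library_diversity",
    "load_strain_registry",
    "nnk_enumerate",
    "reverse_translate",
    "translate_codons",
    "write_strain_registry",
]
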