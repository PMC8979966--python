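"""FASTQ parsing, anchored payload extraction and count-table construction.

Payloads are located by an exact (perfect-match) search for the conserved
anchor; the fixed-length payload immediately 3' of the anchor is the
variant-identifying sequence.  Barcode-pair amplicons carry the MATa
barcode after the forward anchor on the read and the MATalpha barcode
after the reverse anchor on the reverse-complemented read.  Reads are
assigned to registry variants by exact string equality (barcodes and
payloads are designed distinct); an optional Hamming-1 correction exists
but is off by default.

Every read ends in exactly one status — assigned, low_quality, no_anchor
or unassigned_payload — so assigned + unassigned always equals the number
of reads processed.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .screen_model import AmpliconScheme, StrainRecord

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class Status(str, Enum):
    ASSIGNED = "assigned"
    LOW_QUALITY = "low_quality"
    NO_ANCHOR = "no_anchor"
    UNASSIGNED_PAYLOAD = "unassigned_payload"


UNASSIGNED_STATUSES = (Status.LOW_QUALITY, Status.NO_ANCHOR, Status.UNASSIGNED_PAYLOAD)


@dataclass
class ExtractionResult:
    read_id: str
    status: Status
    payload: str | None = None
    pair: tuple[str, str] | None = None  # (a barcode, alpha barcode)
    variant: str | tuple[str, str] | None = None  # strain id(s) after assignment


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) records; transparently handles .gz."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        yield from FastqGeneralIterator(fh)


def mean_quality(qual: str) -> float:
    """Mean Phred score of a Phred+33 quality string."""
    if not qual:
        return 0.0
    arr = np.frombuffer(qual.encode(), dtype=np.uint8)
    return float(arr.mean()) - 33.0


def quality_filter(
    records: Iterable[tuple[str, str, str]], min_mean_q: float = 20.0
) -> Iterator[tuple[str, str, str, bool]]:
    """Tag each record with whether its mean quality reaches the threshold."""
    for title, seq, qual in records:
        yield title, seq, qual, mean_quality(qual) >= min_mean_q


def _payload_after(read: str, anchor: str, payload_len: int) -> str | None:
    idx = read.find(anchor)  # first (5'-most) occurrence wins
    if idx < 0:
        return None
    start = idx + len(anchor)
    if start + payload_len > len(read):
        return None
    return read[start : start + payload_len]


def extract_after_anchor(
    read: str, scheme: AmpliconScheme, read_id: str = ""
) -> ExtractionResult:
    """Extract the payload following an exact anchor match (peptide/cdr3 modes).

    Searches the forward strand first; falls back to the reverse complement
    when the scheme's orientation policy allows it.  Failure is a
    ``no_anchor`` status, never an exception.
    """
    if scheme.mode not in ("peptide", "cdr3"):
        raise ValueError(f"extract_after_anchor needs a payload-mode scheme, got {scheme.mode!r}")
    payload = _payload_after(read, scheme.forward_anchor, scheme.payload_len)
    if payload is None and scheme.orientation_policy == "also_revcomp":
        payload = _payload_after(revcomp(read), scheme.forward_anchor, scheme.payload_len)
    if payload is None:
        return ExtractionResult(read_id, Status.NO_ANCHOR)
    return ExtractionResult(read_id, Status.ASSIGNED, payload=payload)


def extract_barcode_pair(
    read: str, scheme: AmpliconScheme, read_id: str = ""
) -> ExtractionResult:
    """Extract the (MATa, MATalpha) barcode pair from a recombined amplicon.

    The forward barcode follows the forward anchor scanning 5'->3'; the
    reverse barcode follows the reverse anchor on the reverse-complemented
    read.  Both are required; anything less is ``no_anchor``.
    """
    if scheme.mode != "barcode_pair":
        raise ValueError(f"extract_barcode_pair needs a barcode_pair scheme, got {scheme.mode!r}")

    def _both(oriented: str) -> tuple[str, str] | None:
        a = _payload_after(oriented, scheme.forward_anchor, scheme.payload_len)
        if a is None:
            return None
        alpha = _payload_after(
            revcomp(oriented), scheme.reverse_anchor, scheme.reverse_payload_len
        )
        if alpha is None:
            return None
        return a, alpha

    pair = _both(read)
    if pair is None and scheme.orientation_policy == "also_revcomp":
        pair = _both(revcomp(read))
    if pair is None:
        return ExtractionResult(read_id, Status.NO_ANCHOR)
    return ExtractionResult(read_id, Status.ASSIGNED, pair=pair)


class RegistryIndex:
    """Exact-match lookup from payloads / barcodes to strain records.

    The payload index covers only the sequenced side for the given scheme
    mode (pMHC for peptide, TCR for cdr3), and refuses ambiguous payloads.
    """

    def __init__(
        self,
        registry: Sequence[StrainRecord],
        scheme: AmpliconScheme,
        hamming1: bool = False,
    ) -> None:
        self.scheme = scheme
        self.hamming1 = hamming1
        self.by_id = {r.strain_id: r for r in registry}
        self.payload_to_strain: dict[str, str] = {}
        self.barcode_to_strain: dict[str, str] = {}
        if scheme.mode in ("peptide", "cdr3"):
            kind = "pMHC" if scheme.mode == "peptide" else "TCR"
            for r in registry:
                if r.payload_kind != kind:
                    continue
                if r.payload_dna in self.payload_to_strain:
                    other = self.payload_to_strain[r.payload_dna]
                    raise ValueError(
                        f"payload shared by strains {other!r} and {r.strain_id!r}; "
                        "payload-mode assignment would be ambiguous"
                    )
                self.payload_to_strain[r.payload_dna] = r.strain_id
        else:
            for r in registry:
                for bc in r.barcodes:
                    if bc in self.barcode_to_strain:
                        raise ValueError(f"barcode {bc!r} owned by two strains")
                    self.barcode_to_strain[bc] = r.strain_id

    def _lookup(self, table: Mapping[str, str], seq: str) -> str | None:
        hit = table.get(seq)
        if hit is not None or not self.hamming1:
            return hit
        found = None
        for i, orig in enumerate(seq):
            for b in "ACGT":
                if b == orig:
                    continue
                cand = table.get(seq[:i] + b + seq[i + 1 :])
                if cand is not None:
                    if found is not None and found != cand:
                        return None  # ambiguous within Hamming 1
                    found = cand
        return found

    def lookup_payload(self, payload: str) -> str | None:
        return self._lookup(self.payload_to_strain, payload)

    def lookup_barcode(self, barcode: str) -> str | None:
        return self._lookup(self.barcode_to_strain, barcode)


def assign_variant(
    result: ExtractionResult, index: RegistryIndex
) -> ExtractionResult:
    """Resolve an extracted payload or barcode pair to registry identities.

    Barcode pairs map to (MATa strain, MATalpha strain); clones of one
    biological identity keep distinct strain ids here and are merged at the
    grouping stage.
    """
    if result.status is not Status.ASSIGNED:
        return result
    if result.pair is not None:
        a = index.lookup_barcode(result.pair[0])
        alpha = index.lookup_barcode(result.pair[1])
        if a is None or alpha is None:
            return ExtractionResult(result.read_id, Status.UNASSIGNED_PAYLOAD, pair=result.pair)
        return ExtractionResult(
            result.read_id, Status.ASSIGNED, pair=result.pair, variant=(a, alpha)
        )
    strain = index.lookup_payload(result.payload)
    if strain is None:
        return ExtractionResult(
            result.read_id, Status.UNASSIGNED_PAYLOAD, payload=result.payload
        )
    return ExtractionResult(
        result.read_id, Status.ASSIGNED, payload=result.payload, variant=strain
    )


@dataclass
class CountTable:
    """Replicate x variant read counts plus per-replicate failure tallies.

    ``counts`` rows are variant strain ids (payload modes) or a
    (a_strain, alpha_strain) MultiIndex (barcode-pair mode); columns are
    replicate labels.  ``unassigned`` rows are failure statuses.
    """

    counts: pd.DataFrame
    unassigned: pd.DataFrame
    replicate_arms: dict[str, str]

    def total_reads(self) -> pd.Series:
        return self.counts.sum(axis=0) + self.unassigned.sum(axis=0)

    def save(self, out_dir: str | Path, stem: str = "counts") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(out_dir / f"{stem}.tsv", sep="\t")
        self.unassigned.to_csv(out_dir / f"{stem}_unassigned.tsv", sep="\t")


def extract_fastq(
    path: str | Path,
    scheme: AmpliconScheme,
    index: RegistryIndex,
    min_mean_q: float = 20.0,
) -> tuple[Counter, Counter]:
    """Stream one FASTQ through filter -> extract -> assign.

    Returns (variant counts, status tallies); the variant keys are strain
    ids or (a, alpha) strain pairs depending on the scheme mode.
    """
    extract = extract_barcode_pair if scheme.mode == "barcode_pair" else extract_after_anchor
    counts: Counter = Counter()
    statuses: Counter = Counter()
    for title, seq, qual, ok in quality_filter(iter_fastq(path), min_mean_q):
        if not ok:
            statuses[Status.LOW_QUALITY] += 1
            continue
        res = assign_variant(extract(seq, scheme, title), index)
        statuses[res.status] += 1
        if res.status is Status.ASSIGNED:
            counts[res.variant] += 1
    return counts, statuses


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Load a replicate manifest TSV with columns fastq, replicate, arm.

    Relative FASTQ paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"fastq", "replicate", "arm"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    if df["replicate"].duplicated().any():
        raise ValueError("duplicate replicate labels in manifest")
    base = path.parent
    df["fastq"] = [str(p if Path(p).is_absolute() else base / p) for p in df["fastq"]]
    return df


def build_count_table(
    fastq_by_replicate: Mapping[str, str | Path],
    scheme: AmpliconScheme,
    registry: Sequence[StrainRecord],
    replicate_arms: Mapping[str, str] | None = None,
    min_mean_q: float = 20.0,
    hamming1: bool = False,
) -> CountTable:
    """Count assigned reads per replicate over the full registry axis.

    Rows cover every registry variant (or every MATa x MATalpha strain
    combination in barcode-pair mode) so that zero counts are explicit.
    """
    index = RegistryIndex(registry, scheme, hamming1=hamming1)
    if scheme.mode == "barcode_pair":
        a_ids = sorted(r.strain_id for r in registry if r.mating_type == "a")
        alpha_ids = sorted(r.strain_id for r in registry if r.mating_type == "alpha")
        row_index = pd.MultiIndex.from_product(
            [a_ids, alpha_ids], names=["a_strain", "alpha_strain"]
        )
    else:
        kind = "pMHC" if scheme.mode == "peptide" else "TCR"
        row_index = pd.Index(
            sorted(r.strain_id for r in registry if r.payload_kind == kind),
            name="variant_id",
        )
    reps = list(fastq_by_replicate)
    counts = pd.DataFrame(0, index=row_index, columns=reps, dtype=np.int64)
    unassigned = pd.DataFrame(
        0, index=[s.value for s in UNASSIGNED_STATUSES], columns=reps, dtype=np.int64
    )
    unassigned.index.name = "status"
    for rep, path in fastq_by_replicate.items():
        rep_counts, statuses = extract_fastq(path, scheme, index, min_mean_q)
        for key, n in rep_counts.items():
            counts.loc[key, rep] = n
        for status in UNASSIGNED_STATUSES:
            unassigned.loc[status.value, rep] = statuses.get(status, 0)
    arms = dict(replicate_arms) if replicate_arms else {r: "pooled" for r in reps}
    unknown = set(arms) ^ set(reps)
    if replicate_arms is not None and unknown:
        raise ValueError(f"replicate labels mismatch between manifest and files: {sorted(unknown)}")
    return CountTable(counts=counts, unassigned=unassigned, replicate_arms=arms)


__all__ = [
    "CountTable",
    "ExtractionResult",
    "RegistryIndex",
    "Status",
    "UNASSIGNED_STATUSES",
    "assign_variant",
    "build_count_table",
    "extract_after_anchor",
    "extract_barcode_pair",
    "extract_fastq",
    "iter_fastq",
    "mean_quality",
    "quality_filter",
    "read_manifest",
    "revcomp",
]
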