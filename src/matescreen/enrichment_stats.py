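"""Internal-control normalization, group comparison and enrichment calls.

The screen's statistic: within each replicate, a variant's read count is
divided by the count of the stop-codon internal control (a variant that
cannot display its payload and therefore mates only at the background
rate).  Per-replicate ratios are compared between the experimental and
control arms with an unpaired pooled-variance Student t-test; a variant is
called enriched when fold change (ratio of arm means) exceeds the cutoff
and the p-value is below the threshold (defaults: FC > 1, p < 0.05, raw
p-values — Benjamini-Hochberg is an opt-in column).

Library-on-library tables are first grouped: pMHC proportions are computed
per TCR barcode clone, averaged across the clones of a TCR group, then
normalized to the control peptide within each group.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .read_extraction import CountTable
from .screen_model import ScreenDesign, StrainRecord

ENRICHMENT_COLUMNS = [
    "mean_experimental",
    "mean_control",
    "fold_change",
    "t_statistic",
    "p_value",
    "call",
]


def _counts_frame(table: CountTable | pd.DataFrame) -> pd.DataFrame:
    return table.counts if isinstance(table, CountTable) else table


def proportions(table: CountTable | pd.DataFrame) -> pd.DataFrame:
    """Per-replicate fractions of assigned reads; columns sum to 1."""
    counts = _counts_frame(table)
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"replicate(s) with zero assigned reads: {list(zero.index)}")
    return counts / totals


def normalize_to_control(
    table: CountTable | pd.DataFrame, control_id: str, pseudocount: float = 0.0
) -> pd.DataFrame:
    """Per-replicate enrichment ratios: (count + pc) / (control count + pc).

    Identical whether computed from raw counts or from proportions, since
    the replicate total cancels.  A zero control count with pseudocount 0
    is an explicit error (set pseudocount=0.5 to smooth).
    """
    counts = _counts_frame(table)
    if control_id not in counts.index:
        raise ValueError(f"internal control {control_id!r} absent from count table")
    ctrl = counts.loc[control_id].astype(float) + pseudocount
    if (ctrl == 0).any():
        bad = list(ctrl.index[ctrl == 0])
        raise ValueError(
            f"internal control {control_id!r} has zero reads in replicate(s) {bad} "
            "with pseudocount 0; set a pseudocount (e.g. 0.5)"
        )
    return (counts.astype(float) + pseudocount) / ctrl


def group_library_on_library(
    table: CountTable | pd.DataFrame,
    registry: Sequence[StrainRecord],
    control_id: str,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Collapse a (MATa strain x pMHC) table to control-normalized TCR-group ratios.

    Steps: per MATa barcode clone, pMHC read proportions within each
    replicate; mean of those proportions across the clones of each TCR
    group; normalization to the control peptide within each (group,
    replicate).  Returns ratios indexed by (tcr_group, pmhc_variant).
    """
    counts = _counts_frame(table)
    if not isinstance(counts.index, pd.MultiIndex):
        raise ValueError("library-on-library grouping needs a (a_strain, pMHC) MultiIndex table")
    group_of = {r.strain_id: r.group_id for r in registry if r.mating_type == "a"}
    unknown = set(counts.index.get_level_values(0)) - set(group_of)
    if unknown:
        raise ValueError(f"MATa strains missing from registry: {sorted(unknown)}")
    strain_totals = counts.groupby(level=0).sum()
    zero = strain_totals[(strain_totals == 0).any(axis=1)]
    if len(zero):
        raise ValueError(
            f"MATa strain(s) with zero reads in some replicate: {list(zero.index)}; "
            "increase sequencing depth"
        )
    per_strain_prop = counts / strain_totals.reindex(
        counts.index.get_level_values(0)
    ).set_axis(counts.index)
    groups = counts.index.get_level_values(0).map(group_of)
    grouped = per_strain_prop.groupby(
        [pd.Index(groups, name="tcr_group"), counts.index.get_level_values(1)]
    ).mean()
    grouped.index.names = ["tcr_group", "pmhc_variant"]
    pmhc_ids = grouped.index.get_level_values(1).unique()
    if control_id not in pmhc_ids:
        raise ValueError(f"control peptide {control_id!r} absent from table")
    ctrl = grouped.xs(control_id, level="pmhc_variant") + pseudocount
    if (ctrl == 0).any().any():
        raise ValueError(
            f"control peptide {control_id!r} has zero proportion in some "
            "(group, replicate) with pseudocount 0"
        )
    denom = ctrl.reindex(grouped.index.get_level_values(0)).set_axis(grouped.index)
    return (grouped + pseudocount) / denom


def student_t_test(
    x: Sequence[float], y: Sequence[float], tails: str = "two"
) -> tuple[float, float]:
    """Unpaired pooled-variance Student t-test.

    ``tails="two"`` doubles the upper tail of |t|; ``tails="one"`` tests the
    directional alternative mean(x) > mean(y).  Degenerate convention: zero
    pooled variance gives (0, 1) for equal means and p = 0 for unequal
    means.  Requires at least two observations per group.
    """
    if tails not in ("one", "two"):
        raise ValueError(f"tails must be 'one' or 'two', got {tails!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 observations")
    df = nx + ny - 2
    delta = x.mean() - y.mean()
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    if sp2 == 0.0:
        if delta == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, delta), 0.0
    t = delta / math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    if tails == "two":
        p = 2.0 * float(stats.t.sf(abs(t), df))
    else:
        p = float(stats.t.sf(t, df))
    return float(t), min(p, 1.0)


def welch_t_test(
    x: Sequence[float], y: Sequence[float], tails: str = "two"
) -> tuple[float, float]:
    """Welch (unequal-variance) alternative, for sensitivity analyses."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(x, y, equal_var=False,
                          alternative="two-sided" if tails == "two" else "greater")
    return float(res.statistic), float(res.pvalue)


def _fold_change(mx: float, my: float) -> float:
    if my == 0.0:
        return math.inf if mx > 0 else math.nan
    return mx / my


def _call_table(
    rows: Mapping[str, tuple[np.ndarray, np.ndarray]],
    design: ScreenDesign,
    tails: str,
    welch: bool,
    bh: bool,
) -> pd.DataFrame:
    test = welch_t_test if welch else student_t_test
    out = []
    for variant in sorted(rows):
        x, y = rows[variant]
        t, p = test(x, y, tails=tails)
        fc = _fold_change(float(np.mean(x)), float(np.mean(y)))
        call = bool(fc > design.fold_change_cutoff and p < design.p_cutoff)
        out.append(
            {
                "variant_id": variant,
                "mean_experimental": float(np.mean(x)),
                "mean_control": float(np.mean(y)),
                "fold_change": fc,
                "t_statistic": t,
                "p_value": p,
                "call": call,
            }
        )
    df = pd.DataFrame(out, columns=["variant_id", *ENRICHMENT_COLUMNS]).set_index("variant_id")
    if bh and len(df):
        df["adjusted_p"] = stats.false_discovery_control(df["p_value"].to_numpy(), method="bh")
    return df


def call_enrichment(
    ratios: pd.DataFrame,
    replicate_arms: Mapping[str, str],
    design: ScreenDesign,
    tails: str = "two",
    welch: bool = False,
    bh: bool = False,
) -> pd.DataFrame:
    """Enrichment calls for an arm-style screen (variants x replicate ratios).

    ``replicate_arms`` maps each replicate column to ``"experimental"`` or
    ``"control"``.  Returns a variant-indexed frame (lexicographic order)
    with arm means, fold change, t, p and the boolean call.
    """
    exp_cols = [c for c in ratios.columns if replicate_arms.get(c) == "experimental"]
    ctrl_cols = [c for c in ratios.columns if replicate_arms.get(c) == "control"]
    if len(exp_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need >= 2 replicates in each arm")
    rows = {
        str(v): (ratios.loc[v, exp_cols].to_numpy(float), ratios.loc[v, ctrl_cols].to_numpy(float))
        for v in ratios.index
    }
    return _call_table(rows, design, tails, welch, bh)


def call_enrichment_grouped(
    grouped_ratios: pd.DataFrame,
    design: ScreenDesign,
    tails: str = "two",
    welch: bool = False,
    bh: bool = False,
) -> pd.DataFrame:
    """Enrichment calls for a library-on-library screen.

    ``grouped_ratios`` is indexed by (tcr_group, pmhc_variant) with replicate
    columns.  For each pMHC variant, the experimental sample pools the
    replicate ratios of the experimental TCR group(s) and the control sample
    those of the control groups.
    """
    groups = grouped_ratios.index.get_level_values(0)
    missing = (set(design.experimental_groups) | set(design.control_groups)) - set(groups)
    if missing:
        raise ValueError(f"design groups absent from grouped table: {sorted(missing)}")
    rows = {}
    for variant in sorted(grouped_ratios.index.get_level_values(1).unique()):
        x = np.concatenate(
            [grouped_ratios.loc[(g, variant)].to_numpy(float) for g in design.experimental_groups]
        )
        y = np.concatenate(
            [grouped_ratios.loc[(g, variant)].to_numpy(float) for g in design.control_groups]
        )
        rows[str(variant)] = (x, y)
    return _call_table(rows, design, tails, welch, bh)


def null_screen_call_rate(
    n_screens: int,
    n_variants: int = 20,
    read_depth: int = 20_000,
    replicates: int = 3,
    seed: int = 0,
    fold_change_cutoff: float = 1.0,
    p_cutoff: float = 0.05,
) -> float:
    """Empirical type-I error of the enrichment call under a null screen.

    Simulates screens in which every variant mates identically (so every
    apparent enrichment is multinomial sampling noise), runs the real
    normalization + call path on each, and returns the fraction of
    non-control variants called enriched.  Should not exceed the p cutoff
    by more than Monte-Carlo error, since the call additionally requires
    fold change above 1.
    """
    rng = np.random.default_rng(seed)
    variants = [f"v{i:03d}" for i in range(n_variants)]
    control = variants[0]
    design = ScreenDesign(
        experimental_groups=["exp"],
        control_groups=["ctrl"],
        internal_control=control,
        replicates=replicates,
        fold_change_cutoff=fold_change_cutoff,
        p_cutoff=p_cutoff,
    )
    cols = [f"experimental_rep{i}" for i in range(replicates)] + [
        f"control_rep{i}" for i in range(replicates)
    ]
    arms = {c: ("experimental" if c.startswith("exp") else "control") for c in cols}
    prob = np.full(n_variants, 1.0 / n_variants)
    called = 0
    total = 0
    for _ in range(n_screens):
        draws = rng.multinomial(read_depth, prob, size=2 * replicates).T
        counts = pd.DataFrame(draws, index=variants, columns=cols)
        ratios = normalize_to_control(counts, control)
        result = call_enrichment(ratios, arms, design)
        result = result.drop(index=control)
        called += int(result["call"].sum())
        total += len(result)
    return called / total


__all__ = [
    "ENRICHMENT_COLUMNS",
    "null_screen_call_rate",
    "call_enrichment",
    "call_enrichment_grouped",
    "group_library_on_library",
    "normalize_to_control",
    "proportions",
    "student_t_test",
    "welch_t_test",
]
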