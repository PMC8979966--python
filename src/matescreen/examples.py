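"""Benchmark worked examples: reported screen outcomes as reusable fixtures.

Two screens with orthogonally validated outcomes serve as fixed test
cases for the performance module:

* The SL9 position-3 peptide screen against the 868 TCR.  Seven variants
  were called enriched (SL9, 3F, 3L, 3H, 3W, 3Q, 3K); coculture validation
  showed six of the seven activate cognate T cells, and nine library
  members in total activate more than 10% of T cells.  Hence a
  validated-call rate of 6/7 and a sensitivity of 6/9.
* The VaCDR3 TCR screen against SL9.  Fifteen CDR3 mutants were screened,
  twelve were enriched, and all fifteen stain with SL9 tetramer, giving a
  sensitivity of 12/15 = 80%.

Activation fractions other than SL9's (75.6%) are synthetic stand-ins
chosen only to fall on the correct side of the 10% rule; the call sets and
the identities of the named variants are the reported ones.
"""

from __future__ import annotations

from .performance_eval import GroundTruthTable, label_ground_truth
from .synthetic_screen import (
    CDR3_STOP,
    CDR3_STRONG_MUTANTS,
    CDR3_WEAK_MUTANTS,
    PEPTIDE_ACTIVATION,
)

#: Variants called enriched in the peptide screen (FC > 1, p < 0.05).
PEPTIDE_SCREEN_CALLS = frozenset({"SL9", "3F", "3L", "3H", "3W", "3Q", "3K"})


def peptide_screen_example() -> tuple[set[str], GroundTruthTable]:
    """(calls, activation ground truth) for the SL9 position-3 peptide screen."""
    return set(PEPTIDE_SCREEN_CALLS), label_ground_truth(PEPTIDE_ACTIVATION)


#: The fifteen screened CDR3 mutants (three named weak binders; the other
#: twelve octamers are synthetic stand-ins for unnamed enriched mutants).
TCR_SCREEN_MUTANTS = tuple(CDR3_STRONG_MUTANTS) + tuple(CDR3_WEAK_MUTANTS)

#: Mutants called enriched: all but the three named weak binders.
TCR_SCREEN_CALLS = frozenset(CDR3_STRONG_MUTANTS)


def tcr_screen_example() -> tuple[set[str], GroundTruthTable]:
    """(calls, tetramer ground truth) for the VaCDR3 screen.

    All fifteen mutants are tetramer-positive (label fraction 0.5, a binary
    positive stand-in); the stop-codon control is negative.  The wild-type
    receptor is the positive control and is excluded from the comparison,
    matching how the 12/15 sensitivity was counted.
    """
    activation = {m: 0.5 for m in TCR_SCREEN_MUTANTS}
    activation[CDR3_STOP] = 0.0
    return set(TCR_SCREEN_CALLS), label_ground_truth(activation)


__all__ = [
    "PEPTIDE_SCREEN_CALLS",
    "TCR_SCREEN_CALLS",
    "TCR_SCREEN_MUTANTS",
    "peptide_screen_example",
    "tcr_screen_example",
]
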