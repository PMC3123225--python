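"""Closed-form power analysis for microinversion surveys.

Under the Poisson rate model the number of inversions on a branch of
length *t* MY in *L* Mb of sequence is Poisson with mean
``lambda * L * t``, so the chance of seeing at least one is
``1 - exp(-lambda * L * t)`` and the sequence length needed to reach a
target probability P is ``-ln(1 - P) / (lambda * t)``.  With
``n_branches`` short branches of interest, "at least one informative
inversion anywhere" multiplies the exposure by the branch count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ValidationError


@dataclass
class PowerQuery:
    """Inputs of one power computation.

    rate in inversions/Mb/MY, branch_length in MY, target_prob the
    desired chance of >=1 inversion, n_branches the number of branches
    any of which would count.
    """

    rate: float
    branch_length: float
    target_prob: float = 0.95
    n_branches: int = 1

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.branch_length <= 0:
            raise ValidationError("rate and branch_length must be > 0")
        if not 0.0 < self.target_prob < 1.0:
            raise ValidationError("target_prob must be in (0, 1)")
        if self.n_branches < 1:
            raise ValidationError("n_branches must be >= 1")


def prob_at_least_one(rate: float, length_mb: float, branch_length: float,
                      n_branches: int = 1) -> float:
    """P(>=1 inversion) = 1 - exp(-rate * L * t * n_branches)."""
    if rate < 0 or length_mb < 0 or branch_length < 0 or n_branches < 1:
        raise ValidationError("inputs must be non-negative, n_branches >= 1")
    return float(-np.expm1(-rate * length_mb * branch_length * n_branches))


def required_length(query: PowerQuery) -> float:
    """Sequence length (Mb per taxon) to hit the target probability."""
    return float(-np.log1p(-query.target_prob)
                 / (query.rate * query.branch_length * query.n_branches))


def expected_inversions(rate: float, length_mb: float,
                        treelength: float) -> float:
    """Expected inversion count over a whole tree: rate * L * treelength."""
    if rate < 0 or length_mb < 0 or treelength < 0:
        raise ValidationError("inputs must be non-negative")
    return float(rate * length_mb * treelength)


def power_table(rate: float, branch_lengths, target_probs,
                n_branches: int = 1) -> pd.DataFrame:
    """Required length (Mb) over a grid of branch lengths x target probs."""
    rows = []
    for t in branch_lengths:
        for p in target_probs:
            q = PowerQuery(rate, t, p, n_branches)
            rows.append([t, p, n_branches, required_length(q)])
    return pd.DataFrame(rows, columns=["branch_length_my", "target_prob",
                                       "n_branches", "required_length_mb"])
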