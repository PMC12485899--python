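"""Individual-level concordance between introgression-calling methods.

For a shared cohort of individuals with per-individual maps from several
methods, compute the pairwise Jaccard (raw or normalized) per individual,
then aggregate to a mean and population standard deviation per method
pair, retaining the full per-individual distribution.

An individual for whom one method calls nothing contributes Jaccard 0 to
that pair rather than being dropped: absence of calls is itself a
prediction difference, and dropping such individuals would bias the mean
upward. Set ``drop_empty_pairs=True`` to get the dropping behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .compare import jaccard, normalized_jaccard
from .maps import ScoredMap

__all__ = ["CohortMaps", "PairSummary", "individual_jaccard_matrix"]


@dataclass
class CohortMaps:
    """Per-(method, individual) maps for one shared cohort.

    Every method must provide a map — possibly empty — for every
    individual; a missing entry means the cohorts are not actually shared
    and is rejected so that averages are comparable across pairs.
    """

    methods: tuple[str, ...]
    individuals: tuple[str, ...]
    maps: Mapping[tuple[str, str], ScoredMap]

    def __post_init__(self):
        if len(set(self.methods)) != len(self.methods):
            raise ValueError("method names must be unique")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("individual IDs must be unique")
        missing = [
            (m, ind)
            for m in self.methods
            for ind in self.individuals
            if (m, ind) not in self.maps
        ]
        if missing:
            raise ValueError(
                f"cohort not shared: missing maps for {missing[:5]}"
                + (" ..." if len(missing) > 5 else "")
            )

    def get(self, method: str, individual: str) -> ScoredMap:
        return self.maps[(method, individual)]


@dataclass
class PairSummary:
    """Aggregated Jaccard for one method pair across the cohort."""

    method_a: str
    method_b: str
    mean: float
    sd: float
    values: np.ndarray = field(repr=False)  # per-individual, cohort order


def individual_jaccard_matrix(
    cohort: CohortMaps,
    normalized: bool = False,
    drop_empty_pairs: bool = False,
) -> tuple[list[PairSummary], pd.DataFrame]:
    """Per-method-pair mean/SD of per-individual Jaccard similarities.

    Returns the pair summaries and a long-format frame with one row per
    (method_a, method_b, individual, jaccard). SD is the uncorrected
    (population) standard deviation; with a single individual it is 0.
    """
    if not cohort.individuals:
        raise ValueError("cohort has no individuals")
    if len(cohort.methods) < 2:
        raise ValueError("need at least two methods to compare")
    metric = normalized_jaccard if normalized else jaccard
    summaries: list[PairSummary] = []
    rows = []
    for ma, mb in combinations(cohort.methods, 2):
        values = []
        for ind in cohort.individuals:
            a = cohort.get(ma, ind)
            b = cohort.get(mb, ind)
            if drop_empty_pairs and (a.total_bp == 0 or b.total_bp == 0):
                continue
            values.append(metric(a, b))
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise ValueError(f"no usable individuals for pair ({ma}, {mb})")
        summaries.append(
            PairSummary(ma, mb, float(arr.mean()), float(arr.std(ddof=0)), arr)
        )
        used = (
            cohort.individuals
            if not drop_empty_pairs
            else [
                ind
                for ind in cohort.individuals
                if cohort.get(ma, ind).total_bp and cohort.get(mb, ind).total_bp
            ]
        )
        rows.extend(
            {"method_a": ma, "method_b": mb, "individual": ind, "jaccard": v}
            for ind, v in zip(used, arr)
        )
    return summaries, pd.DataFrame(rows)
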