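"""Within-sample binary gene-pair features and the frequency filter.

The feature for a pair (a, b) in sample s is ``1 if expr[a, s] > expr[b, s]
else 0``.  Because it only looks at the ordering of two genes *within* one
sample, any strictly increasing per-sample transform of the expression
values (library-size scaling, log, quantile shifts — the usual face of a
batch effect) leaves the feature matrix bit-identical.  That invariance is
the reason this pipeline needs no cross-cohort normalisation.

Conventions (the indicator is undefined at exact ties and has two possible
orientations per unordered pair; both choices must be fixed for
determinism):

* ties ``Ea == Eb`` emit 0;
* each unordered pair appears exactly once, oriented lexicographically
  (``gene_a < gene_b`` as strings).

Pairs whose "1" frequency on the reference (training) cohort falls outside
[lo, hi] (default 20-80 %, bounds inclusive) are discarded: near-constant
indicators carry no sample variation worth modelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .cohorts_io import ExpressionCohort

__all__ = [
    "GenePair",
    "GenePairMatrix",
    "pair_indicator",
    "enumerate_candidate_pairs",
    "build_pair_matrix",
    "frequency_filter",
    "write_pairs",
    "read_pairs",
]


@dataclass(frozen=True)
class GenePair:
    gene_a: str
    gene_b: str

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError(f"gene pair with identical genes: {self.gene_a}")

    @property
    def label(self) -> str:
        return f"{self.gene_a}|{self.gene_b}"

    @classmethod
    def canonical(cls, a: str, b: str) -> "GenePair":
        return cls(*sorted((str(a), str(b))))


@dataclass
class GenePairMatrix:
    """Binary samples x pairs matrix; ``values`` columns follow ``pairs``."""

    pairs: list  # list[GenePair]
    values: pd.DataFrame  # samples x pair labels, uint8

    @property
    def samples(self) -> list:
        return list(self.values.index)

    @property
    def freq(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float).mean(axis=0)

    def subset(self, keep: Sequence[int]) -> "GenePairMatrix":
        keep = list(keep)
        return GenePairMatrix(
            pairs=[self.pairs[j] for j in keep], values=self.values.iloc[:, keep]
        )


def pair_indicator(ea: float, eb: float) -> int:
    """1 iff ea > eb, else 0 (ties give 0)."""
    return 1 if ea > eb else 0


def enumerate_candidate_pairs(genes: Sequence[str]) -> list:
    """All C(n, 2) unordered pairs in canonical orientation, deterministic
    order (sorted gene list, then combinations)."""
    genes = [str(g) for g in genes]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene symbols in pair enumeration")
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to form pairs")
    return [GenePair(a, b) for a, b in combinations(sorted(genes), 2)]


def build_pair_matrix(cohort: ExpressionCohort, pairs: Sequence[GenePair]) -> GenePairMatrix:
    """Evaluate the pair indicator for every (sample, pair).

    Missing genes are a hard error listing every absent symbol — at predict
    time a cohort that lacks a model gene cannot be scored and silent
    imputation would corrupt the orderings.
    """
    pairs = list(pairs)
    needed = {p.gene_a for p in pairs} | {p.gene_b for p in pairs}
    missing = sorted(needed - set(map(str, cohort.genes)))
    if missing:
        raise KeyError(f"cohort {cohort.cohort_id!r} lacks genes: {missing}")
    expr = cohort.expr
    gene_pos = {g: i for i, g in enumerate(expr.index)}
    mat = expr.to_numpy(dtype=float)
    ia = np.array([gene_pos[p.gene_a] for p in pairs])
    ib = np.array([gene_pos[p.gene_b] for p in pairs])
    vals = (mat[ia].T > mat[ib].T).astype(np.uint8)  # samples x pairs
    values = pd.DataFrame(vals, index=cohort.samples, columns=[p.label for p in pairs])
    return GenePairMatrix(pairs=pairs, values=values)


def frequency_filter(m: GenePairMatrix, lo: float = 0.20, hi: float = 0.80) -> GenePairMatrix:
    """Keep pairs with lo <= freq(ones) <= hi (both bounds inclusive)."""
    if lo >= hi:
        raise ValueError(f"lo ({lo}) must be < hi ({hi})")
    f = m.freq
    keep = np.flatnonzero((f >= lo) & (f <= hi))
    return m.subset(keep)


def write_pairs(pairs: Sequence[GenePair], path) -> None:
    """Persist a pair list as a two-column TSV; part of the frozen model."""
    pd.DataFrame(
        {"gene_a": [p.gene_a for p in pairs], "gene_b": [p.gene_b for p in pairs]}
    ).to_csv(path, sep="\t", index=False)


def read_pairs(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [GenePair(str(a), str(b)) for a, b in zip(df["gene_a"], df["gene_b"])]
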