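"""Within-sample pair-indicator matrices over candidate genes.

For genes A and B and a sample s, the indicator is 1 iff expr(A) >
expr(B) strictly in s (ties and reverse order give 0).  Because the
indicator depends only on the within-sample ordering, the whole matrix
is invariant to any per-sample strictly increasing transform of the
expression values — the property that makes pair signatures portable
across platforms without normalization.

Pairs are stored in canonical orientation (gene_a lexicographically
before gene_b), one row per unordered pair; the reverse orientation is
its deterministic complement away from ties.  Scores are bit-packed as
uint8, so 350 candidates x 500 samples costs ~30 MB.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from rbppairsig.dataio import ExpressionMatrix

__all__ = ["PairIndicatorMatrix", "build_pair_matrix", "filter_constant_pairs", "indicator_matrix"]


@dataclass
class PairIndicatorMatrix:
    """Binary pair-by-sample ordering scores."""

    pairs: list[tuple[str, str]]
    sample_ids: list[str]
    scores: np.ndarray  # uint8, shape (n_pairs, n_samples), entries in {0,1}

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.uint8)
        if self.scores.shape != (len(self.pairs), len(self.sample_ids)):
            raise ValueError("scores shape does not match pairs x samples")
        if self.scores.size and self.scores.max() > 1:
            raise ValueError("scores must be binary")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair_keys(self) -> list[str]:
        return [f"{a}|{b}" for a, b in self.pairs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.pair_keys(), columns=self.sample_ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="pair")

    def subset_samples(self, samples: list[str]) -> "PairIndicatorMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in samples]
        return PairIndicatorMatrix(list(self.pairs), list(samples), self.scores[:, idx])


def indicator_matrix(m: ExpressionMatrix, pairs: list[tuple[str, str]]) -> np.ndarray:
    """Indicator rows for explicitly oriented pairs (uint8, pairs x samples).

    Pairs referencing genes absent from the matrix yield a row of zeros;
    callers that must distinguish absence handle it themselves.
    """
    present = set(m.gene_ids)
    out = np.zeros((len(pairs), m.n_samples), dtype=np.uint8)
    for k, (a, b) in enumerate(pairs):
        if a in present and b in present:
            out[k] = (m.values.loc[a].to_numpy() > m.values.loc[b].to_numpy()).astype(np.uint8)
    return out


def build_pair_matrix(m: ExpressionMatrix, candidates: list[str]) -> PairIndicatorMatrix:
    """All C(n, 2) pair indicators over the candidate genes.

    Candidates are deduplicated and sorted; each unordered pair appears
    once in canonical orientation.  Ties score 0.
    """
    uniq = sorted(set(candidates))
    missing = [g for g in uniq if g not in set(m.gene_ids)]
    if missing:
        raise ValueError(f"candidate gene(s) not in expression matrix: {missing[:5]}")
    if len(uniq) < 2:
        raise ValueError("need at least 2 candidate genes")
    x = m.values.loc[uniq].to_numpy()
    ia, ib = np.triu_indices(len(uniq), k=1)
    scores = (x[ia, :] > x[ib, :]).astype(np.uint8)
    pairs = [(uniq[i], uniq[j]) for i, j in zip(ia, ib)]
    return PairIndicatorMatrix(pairs, list(m.sample_ids), scores)


def filter_constant_pairs(
    p: PairIndicatorMatrix, max_identity: float = 0.90
) -> PairIndicatorMatrix:
    """Drop near-constant pairs.

    A pair is discarded when more than ``max_identity`` of its scores are
    identical, i.e. retained iff max(frac of 1s, frac of 0s) <=
    ``max_identity`` — a pair at exactly the threshold is kept.
    """
    if p.n_pairs == 0:
        return p
    frac1 = p.scores.mean(axis=1)
    keep = np.maximum(frac1, 1.0 - frac1) <= max_identity
    pairs = [pr for pr, k in zip(p.pairs, keep) if k]
    return PairIndicatorMatrix(pairs, list(p.sample_ids), p.scores[keep])
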