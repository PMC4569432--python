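"""Per-sample alpha diversity from the fixed-depth read clustering.

All three metrics derive from one 96%-identity clustering of the sample's
3,000 prepared reads: the observed OTU count, the bias-corrected Chao1
richness estimate built from the singleton/doubleton spectrum, and the
Shannon index (natural log) of the OTU size distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import AlignmentKernel, greedy_cluster
from .records import ReadRecord

OTU_IDENTITY = 0.96


@dataclass
class DiversityResult:
    sample_id: str
    observed_otus: int
    chao1: float
    shannon: float
    singletons: int
    doubletons: int


def observed_otus(reads: Sequence[ReadRecord], threshold: float = OTU_IDENTITY,
                  expected_depth: int = 3000,
                  kernel: AlignmentKernel | None = None,
                  ) -> tuple[int, list[int]]:
    """OTU count and size spectrum from greedy clustering at the threshold.

    The rarefaction contract is strict: the input must contain exactly
    ``expected_depth`` reads so counts are comparable across samples.
    """
    if len(reads) != expected_depth:
        raise ValueError(
            f"expected exactly {expected_depth} reads, got {len(reads)} "
            f"(sample {reads[0].sample_id if reads else '?'})")
    clusters = greedy_cluster([r.id for r in reads],
                              [r.sequence for r in reads],
                              threshold, kernel=kernel)
    spectrum = sorted((len(c.members) for c in clusters), reverse=True)
    return len(clusters), spectrum


def chao1(spectrum: Sequence[int]) -> float:
    """Bias-corrected Chao1: S_obs + F1 (F1 - 1) / (2 (F2 + 1))."""
    s_obs = len(spectrum)
    f1 = sum(1 for s in spectrum if s == 1)
    f2 = sum(1 for s in spectrum if s == 2)
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts: Sequence[float]) -> float:
    """Shannon entropy H = -sum p ln p in nats; zero counts contribute 0."""
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative counts")
    total = arr.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero vector")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


def sample_diversity(sample_id: str, reads: Sequence[ReadRecord],
                     threshold: float = OTU_IDENTITY,
                     expected_depth: int = 3000,
                     kernel: AlignmentKernel | None = None) -> DiversityResult:
    n, spectrum = observed_otus(reads, threshold, expected_depth, kernel)
    return DiversityResult(
        sample_id=sample_id,
        observed_otus=n,
        chao1=chao1(spectrum),
        shannon=shannon(spectrum),
        singletons=sum(1 for s in spectrum if s == 1),
        doubletons=sum(1 for s in spectrum if s == 2),
    )


def diversity_frame(results: Sequence[DiversityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.sample_id, r.observed_otus, r.chao1, r.shannon, r.singletons,
          r.doubletons) for r in results],
        columns=["sample_id", "observed", "chao1", "shannon", "F1", "F2"],
    ).set_index("sample_id")
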