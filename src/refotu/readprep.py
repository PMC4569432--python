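"""Per-sample read QC: mean-quality filtering, fixed-depth subsampling and
IUPAC-aware primer trimming.

The profiling contract downstream is a fixed depth of 3,000 reads per sample
with mean Phred quality strictly above 25, with both amplification primers
removed.  Subsampling is uniform without replacement and reproducible per
sample: the RNG substream is derived from the run seed plus a stable hash of
the sample id, so any single sample can be regenerated in isolation.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .alignment import iupac_match, reverse_complement
from .records import ReadRecord
from .simdata import FORWARD_PRIMER, REVERSE_PRIMER, substream

DEFAULT_DEPTH = 3000
DEFAULT_MIN_MEAN_Q = 25.0


class InsufficientDepthError(ValueError):
    """Raised when a sample has fewer filter-passed reads than the depth."""


def quality_filter(reads: Sequence[ReadRecord],
                   min_mean_q: float = DEFAULT_MIN_MEAN_Q) -> list[ReadRecord]:
    """Keep reads whose arithmetic mean quality is strictly above the cutoff."""
    out = []
    for r in reads:
        if len(r.qualities) == 0:
            raise ValueError(f"read {r.id}: missing quality values")
        if r.mean_quality > min_mean_q:
            out.append(r)
    return out


def subsample(reads: Sequence[ReadRecord], depth: int = DEFAULT_DEPTH,
              seed: int = 0, sample_id: str | None = None) -> list[ReadRecord]:
    """Uniform sample of exactly ``depth`` reads, without replacement.

    Selected reads keep their content bit-exactly and their original
    relative order.
    """
    if sample_id is None:
        sample_id = reads[0].sample_id if reads else ""
    if len(reads) < depth:
        raise InsufficientDepthError(
            f"sample {sample_id!r}: {len(reads)} reads < required depth {depth}")
    if len(reads) == depth:
        return list(reads)
    rng = substream(seed, "subsample", sample_id)
    keep = np.sort(rng.choice(len(reads), size=depth, replace=False))
    return [reads[i] for i in keep]


def _count_mismatches(segment: str, primer: str) -> int:
    return sum(0 if iupac_match(p, b) else 1 for p, b in zip(primer, segment))


def trim_primers(read: ReadRecord,
                 fwd: str = FORWARD_PRIMER,
                 rev: str = REVERSE_PRIMER,
                 max_mismatch: int = 2) -> ReadRecord | None:
    """Remove primer spans; ``None`` if the forward primer does not match.

    The forward primer must match at the 5' end (IUPAC-aware, at most
    ``max_mismatch`` mismatches).  The reverse complement of the reverse
    primer is trimmed from the 3' end when present; pyrosequencing reads that
    stop short of it are kept untrimmed at the 3' side.  Qualities follow the
    bases.
    """
    seq = read.sequence
    if len(seq) < len(fwd) + 1:
        return None
    if _count_mismatches(seq[:len(fwd)], fwd) > max_mismatch:
        return None
    start = len(fwd)
    end = len(seq)
    rc = reverse_complement(rev)
    if end - start >= len(rc):
        if _count_mismatches(seq[end - len(rc):], rc) <= max_mismatch:
            end -= len(rc)
    if end <= start:
        return None
    quals = np.asarray(read.qualities)[start:end] if len(read.qualities) else []
    return ReadRecord(id=read.id, sequence=seq[start:end], qualities=quals,
                      sample_id=read.sample_id)


def trim_sample(reads: Sequence[ReadRecord], fwd: str = FORWARD_PRIMER,
                rev: str = REVERSE_PRIMER,
                max_mismatch: int = 2) -> tuple[list[ReadRecord], int]:
    """Trim every read; returns (trimmed reads, number rejected)."""
    out, rejected = [], 0
    for r in reads:
        t = trim_primers(r, fwd, rev, max_mismatch)
        if t is None:
            rejected += 1
        else:
            out.append(t)
    return out, rejected


def prepare_sample(reads: Sequence[ReadRecord], depth: int = DEFAULT_DEPTH,
                   min_mean_q: float = DEFAULT_MIN_MEAN_Q, seed: int = 0,
                   sample_id: str | None = None, fwd: str = FORWARD_PRIMER,
                   rev: str = REVERSE_PRIMER) -> tuple[list[ReadRecord], dict[str, int]]:
    """Quality filter -> primer trim -> subsample, with stage accounting.

    Trimming precedes the fixed-depth draw so that primer-rejected reads
    cannot leave a sample short of the exact profiling depth.
    """
    passed = quality_filter(reads, min_mean_q)
    trimmed, rejected = trim_sample(passed, fwd=fwd, rev=rev)
    chosen = subsample(trimmed, depth, seed, sample_id)
    stats = {
        "total": len(reads),
        "filter_passed": len(passed),
        "primer_rejected": rejected,
        "subsampled": len(chosen),
        "prepared": len(chosen),
    }
    return chosen, stats
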