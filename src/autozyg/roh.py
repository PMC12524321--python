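"""Sliding-window detection of runs of homozygosity (ROH).

The scan mirrors the classic SNP-array procedure: 50-SNP windows slide
along each chromosome; a window is called homozygous if it contains at most
one heterozygote and at most five missing genotypes; a SNP is flagged as
inside a run when at least 5% of the windows covering it are homozygous.
Flagged runs are then assembled into segments subject to minimum length
(1 Mb), minimum SNP count (15), maximum inter-SNP gap (1 Mb) and maximum
density (one SNP per 200 kb).  ``F_ROH`` is total segment length divided by
the autosomal genome length (2410 Mb for the horse assembly used here), and
segments are classed by length — longer segments indicate more recent
common ancestors because recombination has had fewer meioses to break them
up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, MarkerMap

#: (lower bound bp, class label, inbreeding-age label); half-open upwards,
#: ties belong to the upper class.
LENGTH_CLASSES = [
    (16_000_000, ">=16Mb", "very_recent"),
    (8_000_000, "8-16Mb", "recent"),
    (4_000_000, "4-8Mb", "intermediate"),
    (2_000_000, "2-4Mb", "ancient"),
    (0, "1-2Mb", "ancient"),
]
CLASS_LABELS = [c for _, c, _ in LENGTH_CLASSES][::-1]


@dataclass
class ROHParams:
    """Scan constants; defaults follow the equine SNP-array convention."""

    min_length_bp: int = 1_000_000
    min_snps: int = 15
    max_gap_bp: int = 1_000_000
    max_density_bp_per_snp: int = 200_000
    window_snps: int = 50
    window_max_het: int = 1
    window_max_missing: int = 5
    hit_threshold: float = 0.05
    genome_length_bp: int = 2_410_000_000


@dataclass
class ROHSegment:
    individual: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        # span of the bounding SNPs, inclusive of both end positions
        return self.end_bp - self.start_bp + 1

    @property
    def length_class(self) -> str:
        for lower, label, _ in LENGTH_CLASSES:
            if self.length_bp >= lower:
                return label
        return LENGTH_CLASSES[-1][1]  # pragma: no cover

    @property
    def age_label(self) -> str:
        for lower, _, age in LENGTH_CLASSES:
            if self.length_bp >= lower:
                return age
        return LENGTH_CLASSES[-1][2]  # pragma: no cover


def window_flags(genotypes: np.ndarray, params: ROHParams | None = None) -> np.ndarray:
    """Per-SNP boolean "inside a homozygous run" for one individual on one
    position-sorted chromosome.

    Only fully contained windows are formed; the hit-rate denominator for a
    SNP is the number of windows that actually cover it.  A chromosome with
    fewer SNPs than the window size forms zero windows and gets no flags.
    """
    p = params or ROHParams()
    g = np.asarray(genotypes)
    n = g.size
    w = p.window_snps
    if n < w:
        return np.zeros(n, dtype=bool)
    het = (g == 1).astype(np.int64)
    mis = (g == MISSING).astype(np.int64)
    # counts per window via cumulative sums; window j covers SNPs [j, j+w)
    chet = np.concatenate(([0], np.cumsum(het)))
    cmis = np.concatenate(([0], np.cumsum(mis)))
    hom_win = ((chet[w:] - chet[:-w]) <= p.window_max_het) & \
              ((cmis[w:] - cmis[:-w]) <= p.window_max_missing)
    chom = np.concatenate(([0], np.cumsum(hom_win.astype(np.int64))))
    idx = np.arange(n)
    first = np.maximum(0, idx - w + 1)
    last = np.minimum(idx, n - w)
    n_windows = last - first + 1
    n_hom = chom[last + 1] - chom[first]
    return n_hom / n_windows >= p.hit_threshold


def assemble_segments(
    flags: np.ndarray,
    positions_bp: np.ndarray,
    params: ROHParams | None = None,
    individual: str = "",
    chrom: str = "",
) -> list[ROHSegment]:
    """Assemble flagged SNP runs into ROH segments.

    Maximal runs of flagged SNPs are split where the inter-SNP gap exceeds
    ``max_gap_bp`` and retained iff span >= ``min_length_bp``, SNP count >=
    ``min_snps`` and span/SNP <= ``max_density_bp_per_snp``.  Heterozygote
    and missing content is governed entirely by the window flags.
    """
    p = params or ROHParams()
    flags = np.asarray(flags, dtype=bool)
    pos = np.asarray(positions_bp, dtype=np.int64)
    segments: list[ROHSegment] = []
    i = 0
    n = flags.size
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and flags[j + 1] and pos[j + 1] - pos[j] <= p.max_gap_bp:
            j += 1
        length = int(pos[j] - pos[i] + 1)
        n_snps = j - i + 1
        if (length >= p.min_length_bp and n_snps >= p.min_snps
                and length / n_snps <= p.max_density_bp_per_snp):
            segments.append(ROHSegment(individual, chrom, int(pos[i]),
                                       int(pos[j]), n_snps))
        i = j + 1
    return segments


def detect_roh(
    G: GenotypeMatrix,
    M: MarkerMap,
    params: ROHParams | None = None,
) -> list[ROHSegment]:
    """Window scan + segment assembly for every individual and chromosome."""
    p = params or ROHParams()
    segments: list[ROHSegment] = []
    for chrom in M.chroms:
        idx = M.chrom_indices(chrom)
        pos = M.frame["bp"].to_numpy()[idx]
        sub = G.values[:, idx]
        for i, ind in enumerate(G.individual_ids):
            flags = window_flags(sub[i], p)
            segments.extend(assemble_segments(flags, pos, p, ind, chrom))
    return segments


def segments_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.individual, s.chrom, s.start_bp, s.end_bp, s.n_snps,
          s.length_bp, s.length_class, s.age_label) for s in segments],
        columns=["individual", "chrom", "start_bp", "end_bp", "n_snps",
                 "length_bp", "length_class", "age_label"],
    )


def f_roh(
    segments: list[ROHSegment],
    individual_ids: list[str],
    params: ROHParams | None = None,
) -> pd.DataFrame:
    """Total and length-class F_ROH per individual.

    ``F_ROH = sum(length_bp) / genome_length_bp``; the class columns
    partition the total exactly.  Individuals without segments get zeros.
    """
    p = params or ROHParams()
    cols = ["f_roh"] + [f"f_roh_{c}" for c in CLASS_LABELS]
    out = pd.DataFrame(0.0, index=list(individual_ids), columns=cols)
    for s in segments:
        if s.individual not in out.index:
            continue
        share = s.length_bp / p.genome_length_bp
        out.loc[s.individual, "f_roh"] += share
        out.loc[s.individual, f"f_roh_{s.length_class}"] += share
    out.index.name = "individual"
    return out
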