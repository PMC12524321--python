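"""Genotype/map ingestion and the SNP-array quality-control cascade.

Genotypes live in a dense ``individuals x markers`` matrix coded as counts
of the reference allele {0, 1, 2} with -1 for missing; the marker map keeps
chromosome, identifier and bp position per marker.  The QC cascade applies,
in a fixed documented order: autosome restriction, SNP call rate, the exact
Hardy-Weinberg test, individual missingness, and minor-allele-frequency
filtering.  A method-of-moments IBS/IBD screen flags duplicate samples and
close relatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class MarkerMap:
    """Per-marker chromosome, id and physical position.

    Positions must be strictly increasing within a chromosome; genetic
    positions (Morgan) are derived from bp with a constant unless a genetic
    map is supplied.
    """

    frame: pd.DataFrame  # columns: chrom (str), snp_id (str), bp (int)

    def __post_init__(self) -> None:
        need = {"chrom", "snp_id", "bp"}
        if not need <= set(self.frame.columns):
            raise ValueError(f"marker map needs columns {sorted(need)}")
        self.frame = self.frame.reset_index(drop=True)
        for chrom, grp in self.frame.groupby("chrom", sort=False):
            if not grp["bp"].is_monotonic_increasing or grp["bp"].duplicated().any():
                raise ValueError(f"positions not strictly increasing on {chrom}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.frame["chrom"]))

    def chrom_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.frame["chrom"] == chrom).to_numpy())

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.frame.iloc[idx].reset_index(drop=True))

    def morgan_positions(self, chrom: str, bp_per_morgan: float = 1e8) -> np.ndarray:
        bp = self.frame["bp"].to_numpy()[self.chrom_indices(chrom)]
        return bp / bp_per_morgan


@dataclass
class GenotypeMatrix:
    """Reference-allele dosage matrix, individuals x markers, -1 = missing."""

    individual_ids: list[str]
    marker_ids: list[str]
    values: np.ndarray  # int8, shape (n_ind, n_markers)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.individual_ids), len(self.marker_ids)):
            raise ValueError("genotype matrix shape does not match id lists")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def allele_freqs(self) -> np.ndarray:
        """In-sample reference allele frequency per marker (non-missing)."""
        ok = self.values != MISSING
        alt = np.where(ok, self.values, 0).sum(axis=0)
        denom = 2.0 * ok.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(denom > 0, alt / denom, np.nan)

    def subset(self, ind_idx=None, marker_idx=None) -> "GenotypeMatrix":
        ind_idx = np.arange(self.n_individuals) if ind_idx is None else np.asarray(ind_idx)
        marker_idx = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeMatrix(
            [self.individual_ids[i] for i in ind_idx],
            [self.marker_ids[j] for j in marker_idx],
            self.values[np.ix_(ind_idx, marker_idx)],
        )


@dataclass
class QCThresholds:
    """Cut-offs for the genotype QC cascade (all proportions in [0, 1])."""

    snp_call_rate_min: float = 0.90
    hwe_p_min: float = 1e-6
    ind_missing_max: float = 0.10
    maf_min: float = 0.01
    dup_pi_hat: float = 0.95
    het_outlier_z: float = 3.0


def read_genotypes(ped_file, map_file, reference_alleles: dict[str, str] | None = None):
    """Read PED/MAP text files into a :class:`GenotypeMatrix` + :class:`MarkerMap`.

    PED rows: fid, iid, sire, dam, sex, phenotype, then two allele columns
    per marker; allele "0" means missing.  Coding is deterministic: the
    first non-missing allele seen at a marker becomes the reference allele,
    unless ``reference_alleles`` maps marker id -> allele.

    Raises ``ValueError`` on triallelic markers or rows of the wrong length.
    """
    mp = pd.read_csv(map_file, sep=r"\s+", header=None, dtype=str,
                     names=["chrom", "snp_id", "cm", "bp"])
    mmap = MarkerMap(pd.DataFrame({
        "chrom": mp["chrom"], "snp_id": mp["snp_id"],
        "bp": mp["bp"].astype(np.int64),
    }))
    n_markers = len(mmap)
    marker_ids = list(mmap.frame["snp_id"])
    ref: list[str | None] = [
        reference_alleles.get(m) if reference_alleles else None for m in marker_ids
    ]
    alt: list[str | None] = [None] * n_markers

    ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(ped_file) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise ValueError(
                    f"{ped_file} line {lineno}: expected {6 + 2 * n_markers} "
                    f"fields, found {len(parts)}")
            ids.append(parts[1])
            alleles = parts[6:]
            row = np.full(n_markers, MISSING, dtype=np.int8)
            for j in range(n_markers):
                a1, a2 = alleles[2 * j], alleles[2 * j + 1]
                if a1 == "0" or a2 == "0":
                    continue
                for a in (a1, a2):
                    if ref[j] is None:
                        ref[j] = a
                    elif a != ref[j] and alt[j] is None:
                        alt[j] = a
                    elif a not in (ref[j], alt[j]):
                        raise ValueError(
                            f"marker {marker_ids[j]} has more than two "
                            f"alleles ({ref[j]}, {alt[j]}, {a})")
                row[j] = (a1 == ref[j]) + (a2 == ref[j])
            rows.append(row)
    G = GenotypeMatrix(ids, marker_ids,
                       np.vstack(rows) if rows else np.empty((0, n_markers), np.int8))
    return G, mmap


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    The p-value is the summed probability, over heterozygote counts with
    the correct parity given the observed allele counts, of every
    configuration no more probable than the observed one (the standard
    two-sided exact test; no mid-p correction).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotypes")
    n_a = 2 * n_hom_ref + n_het  # reference allele count
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0
    # log P(n_het | allele counts) up to a constant, over the parity class
    hets = np.arange(rare % 2, rare + 1, 2)
    log_p = (_lf(n) - _lf((n_a - hets) // 2) - _lf(hets) - _lf((2 * n - n_a - hets) // 2)
             + hets * math.log(2.0))
    log_p -= log_p.max()
    probs = np.exp(log_p)
    probs /= probs.sum()
    obs = probs[np.flatnonzero(hets == n_het)[0]]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def _lf(x) -> np.ndarray:
    from scipy.special import gammaln
    return gammaln(np.asarray(x, dtype=float) + 1.0)


AUTOSOME_EXCLUDE = {"X", "Y", "MT", "M", "XY", "0"}


def is_autosome(chrom: str) -> bool:
    c = str(chrom).upper().removeprefix("CHR")
    return c not in AUTOSOME_EXCLUDE


@dataclass
class QCLogEntry:
    step: str
    removed: int
    remaining: int
    detail: str = ""


def qc_cascade(
    G: GenotypeMatrix,
    M: MarkerMap,
    thresholds: QCThresholds | None = None,
) -> tuple[GenotypeMatrix, MarkerMap, list[QCLogEntry]]:
    """Single-pass QC cascade in fixed order: non-autosomes out, SNP call
    rate, HWE exact test, individual missingness, MAF.

    Per-SNP statistics are not recomputed after individual removal (one
    pass, order as listed); the log records counts removed at each step.
    Raises if no marker survives.
    """
    t = thresholds or QCThresholds()
    log: list[QCLogEntry] = []

    auto = np.array([is_autosome(c) for c in M.frame["chrom"]])
    keep_m = np.flatnonzero(auto)
    log.append(QCLogEntry("autosomes", int((~auto).sum()), len(keep_m),
                          "non-autosomal markers removed"))
    G = G.subset(marker_idx=keep_m)
    M = M.subset(keep_m)

    ok = G.values != MISSING
    call_rate = ok.mean(axis=0) if G.n_individuals else np.ones(G.n_markers)
    keep = call_rate >= t.snp_call_rate_min
    log.append(QCLogEntry("snp_call_rate", int((~keep).sum()), int(keep.sum()),
                          f"call rate < {t.snp_call_rate_min}"))
    G = G.subset(marker_idx=np.flatnonzero(keep))
    M = M.subset(np.flatnonzero(keep))

    v = G.values
    n_rr = (v == 2).sum(axis=0)
    n_ra = (v == 1).sum(axis=0)
    n_aa = (v == 0).sum(axis=0)
    hwe_p = np.array([
        hwe_exact_test(int(a), int(b), int(c)) if a + b + c > 0 else 1.0
        for a, b, c in zip(n_rr, n_ra, n_aa)
    ])
    keep = hwe_p >= t.hwe_p_min
    log.append(QCLogEntry("hwe", int((~keep).sum()), int(keep.sum()),
                          f"exact HWE p < {t.hwe_p_min}"))
    G = G.subset(marker_idx=np.flatnonzero(keep))
    M = M.subset(np.flatnonzero(keep))

    miss = (G.values == MISSING).mean(axis=1) if G.n_markers else np.zeros(G.n_individuals)
    keep_i = miss <= t.ind_missing_max
    log.append(QCLogEntry("ind_missing", int((~keep_i).sum()), int(keep_i.sum()),
                          f"individual missingness > {t.ind_missing_max}"))
    G = G.subset(ind_idx=np.flatnonzero(keep_i))

    freqs = G.allele_freqs()
    maf = np.fmin(freqs, 1.0 - freqs)
    keep = np.nan_to_num(maf, nan=0.0) >= t.maf_min
    log.append(QCLogEntry("maf", int((~keep).sum()), int(keep.sum()),
                          f"MAF < {t.maf_min}"))
    G = G.subset(marker_idx=np.flatnonzero(keep))
    M = M.subset(np.flatnonzero(keep))

    if G.n_markers == 0:
        raise ValueError("no markers remain after quality control")
    return G, M, log


def qc_log_frame(log: list[QCLogEntry]) -> pd.DataFrame:
    return pd.DataFrame([(e.step, e.removed, e.remaining, e.detail) for e in log],
                        columns=["step", "removed", "remaining", "detail"])


def ibs_screen(G: GenotypeMatrix, dup_pi_hat: float = 0.95) -> pd.DataFrame:
    """Method-of-moments IBD estimation for every pair of individuals.

    Decomposes observed IBS-sharing counts into P(IBD=0,1,2) using sample
    allele frequencies (the classic PLINK ``--genome`` estimator) and
    reports PI_HAT = P(IBD=2) + P(IBD=1)/2.  Pairs with PI_HAT above
    ``dup_pi_hat`` are flagged as potential duplicates; nothing is removed.
    """
    v = G.values
    n, m = v.shape
    p = G.allele_freqs()
    ok = np.isfinite(p) & (p > 0) & (p < 1)
    v = v[:, ok]
    p = p[ok]
    q = 1.0 - p

    # expected IBS-class proportions for an unrelated pair (IBD=0), and the
    # conditional expectations used to peel IBD=1 and IBD=2 (Purcell et al.)
    e00 = 2 * p**2 * q**2  # P(IBS=0 | IBD=0) summed over loci
    e10 = 4 * p**3 * q + 4 * p * q**3
    e20 = p**4 + q**4 + 4 * p**2 * q**2
    e11 = 2 * p**2 * q + 2 * p * q**2
    e21 = p**3 + q**3 + p**2 * q + p * q**2

    rows = []
    miss = v == MISSING
    for i in range(n):
        for j in range(i + 1, n):
            use = ~(miss[i] | miss[j])
            nm = int(use.sum())
            if nm == 0:
                continue
            gi, gj = v[i, use], v[j, use]
            diff = np.abs(gi - gj)
            ibs0 = int((diff == 2).sum())
            ibs1 = int((diff == 1).sum())
            ibs2 = nm - ibs0 - ibs1
            s00, s10, s20 = e00[use].sum(), e10[use].sum(), e20[use].sum()
            s11, s21 = e11[use].sum(), e21[use].sum()
            p0 = ibs0 / s00 if s00 > 0 else 0.0
            p1 = (ibs1 - p0 * s10) / s11 if s11 > 0 else 0.0
            p2 = (ibs2 - p0 * s20 - p1 * s21) / nm
            z = np.clip([p0, p1, p2], 0.0, None)
            tot = z.sum()
            z = z / tot if tot > 0 else np.array([1.0, 0.0, 0.0])
            pi_hat = z[2] + 0.5 * z[1]
            rows.append((G.individual_ids[i], G.individual_ids[j], nm,
                         ibs0, ibs1, ibs2, z[0], z[1], z[2], pi_hat,
                         pi_hat >= dup_pi_hat))
    return pd.DataFrame(rows, columns=[
        "id1", "id2", "n_used", "ibs0", "ibs1", "ibs2",
        "p_ibd0", "p_ibd1", "p_ibd2", "pi_hat", "flag_duplicate",
    ])
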