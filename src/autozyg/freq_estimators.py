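"""SNP-by-SNP inbreeding estimators.

F_HOM contrasts the observed homozygote count with its Hardy-Weinberg
expectation, ``F_HOM = (O_HOM - E_HOM) / (m - E_HOM)`` with
``E_HOM = sum_j p_j^2 + (1 - p_j)^2`` over an individual's non-missing
loci.  F_GRM is the diagonal of the VanRaden method-I genomic relationship
matrix minus one: with centred genotypes ``Z = G - 2p``,
``G = Z Z' / (2 sum_j p_j (1 - p_j))`` and ``F_GRM(i) = G_ii - 1``.
Both can be negative: they measure deviation from the average allele
frequency in the population, not segment coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class HomStats:
    """Per-individual homozygosity counts: observed, non-missing loci,
    expected under HWE."""

    ids: list[str]
    o_hom: np.ndarray
    m: np.ndarray
    e_hom: np.ndarray


@dataclass
class GRM:
    """VanRaden-I genomic relationship matrix with its scaling denominator."""

    ids: list[str]
    values: np.ndarray
    denominator: float

    def diagonal(self) -> pd.Series:
        return pd.Series(np.diag(self.values), index=self.ids)

    def to_long_frame(self) -> pd.DataFrame:
        n = len(self.ids)
        ii, jj = np.triu_indices(n)
        return pd.DataFrame({
            "id_i": [self.ids[i] for i in ii],
            "id_j": [self.ids[j] for j in jj],
            "g": self.values[ii, jj],
        })


def expected_hom(freqs: np.ndarray, nonmissing: np.ndarray) -> np.ndarray:
    """HWE-expected homozygote count per individual.

    ``freqs``: reference allele frequency per marker; ``nonmissing``:
    boolean (n_ind, n_markers) mask of typed loci.  Fixed markers
    (p in {0, 1}) contribute 1.0 and raise a warning — they should have
    been MAF-filtered upstream.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs <= 0) | (freqs >= 1)):
        warnings.warn("fixed markers (p=0 or 1) contribute E_HOM of 1.0; "
                      "apply a MAF filter upstream", stacklevel=2)
    per_marker = freqs**2 + (1.0 - freqs) ** 2
    return nonmissing @ per_marker


def hom_stats(G: GenotypeMatrix, freqs: np.ndarray | None = None) -> HomStats:
    """Observed/expected homozygosity per individual.

    Frequencies default to the in-sample estimate; supply founder or base
    population frequencies for unbiased simulation checks.
    """
    if freqs is None:
        freqs = G.allele_freqs()
    freqs = np.asarray(freqs, dtype=float)
    ok = (G.values != MISSING) & np.isfinite(freqs)
    o_hom = ((G.values == 0) | (G.values == 2))[:, :] & ok
    return HomStats(
        ids=list(G.individual_ids),
        o_hom=o_hom.sum(axis=1).astype(float),
        m=ok.sum(axis=1).astype(float),
        e_hom=expected_hom(freqs[np.isfinite(freqs)], ok[:, np.isfinite(freqs)]),
    )


def f_hom(stats: HomStats) -> pd.Series:
    """``(O_HOM - E_HOM) / (m - E_HOM)``; NaN where the denominator is 0."""
    denom = stats.m - stats.e_hom
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(np.abs(denom) > 1e-12,
                     (stats.o_hom - stats.e_hom) / denom, np.nan)
    return pd.Series(f, index=stats.ids, name="f_hom")


def vanraden_grm(G: GenotypeMatrix, freqs: np.ndarray | None = None) -> GRM:
    """VanRaden method-I GRM from centred genotypes.

    Missing genotypes are set to ``2p`` (zero after centring), so they do
    not contribute to relationships.  Raises on a zero denominator
    (all markers fixed).
    """
    if freqs is None:
        freqs = G.allele_freqs()
    freqs = np.asarray(freqs, dtype=float)
    ok = np.isfinite(freqs)
    v = G.values[:, ok].astype(float)
    p = freqs[ok]
    Z = np.where(v == MISSING, 0.0, v - 2.0 * p)
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("GRM denominator 2*sum(p(1-p)) is zero; "
                         "all markers fixed")
    return GRM(list(G.individual_ids), (Z @ Z.T) / denom, denom)


def f_grm(grm: GRM) -> pd.Series:
    """``F_GRM(i) = G_ii - 1``; negatives are legitimate."""
    return pd.Series(np.diag(grm.values) - 1.0, index=grm.ids, name="f_grm")
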