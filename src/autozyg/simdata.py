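"""Pedigree simulation and gene-dropping with exact IBD bookkeeping.

The generator emulates the data the estimators were designed for: a small
closed population with deep consanguinity loops, SNP-array genotypes at
desk scale, and founder-derived IBD tracts spanning very recent (tens of
Mb) to ancient (< 2 Mb) coalescence.  Founder haplotypes carry unique
labels, every transmitted segment records its full chain of haplotype
copies back to the founder, and crossovers fall as a Poisson process on the
genetic map (Haldane, no interference).  Because identity is defined by
founder labels, identity-by-state by chance is excluded from the truth —
exactly the autozygosity concept the estimators target.  Genotyping error
(symmetric single-allele flips) and missingness are applied only after the
truth is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, MarkerMap
from .pedigree import Pedigree, PedigreeRecord, build_a_matrix

import datetime as _dt


@dataclass
class SimConfig:
    """Study-scale defaults: 10 chromosomes of 100 Mb (1 Morgan at
    1 cM/Mb) with 2,000 evenly spaced SNPs each (~20K markers), a closed
    population of 30 founders bred for 5 generations of 50 offspring."""

    n_founders: int = 30
    n_generations: int = 5
    n_per_generation: int = 50
    mating_design: str | list[dict] = "random"
    n_chromosomes: int = 10
    chrom_length_bp: int = 100_000_000
    n_snps_per_chrom: int = 2_000
    maf_min: float = 0.05
    genotyping_error: float = 0.0
    missing_rate: float = 0.0
    bp_per_morgan: float = 1e8
    base_year: int = 2000
    years_per_generation: int = 4
    seed: int = 0


@dataclass
class TruthSet:
    """Ground truth recorded during gene dropping.

    ``autozygous_fraction``: per-individual share of the genome where the
    two haplotypes descend from the same founder haplotype.  ``tracts``:
    the underlying intervals with exact generations-to-coalescence g (mean
    of the two path lengths to the most recent common haplotype copy).
    ``true_f_ped`` is the expected inbreeding from the full simulated
    pedigree.
    """

    autozygous_fraction: pd.Series
    tracts: pd.DataFrame
    true_f_ped: pd.Series
    founder_freqs: np.ndarray = field(default=None, repr=False)

    def fraction_check(self, genome_bp: int) -> pd.Series:
        tot = self.tracts.groupby("individual")["length_bp"].sum()
        return tot.reindex(self.autozygous_fraction.index, fill_value=0) / genome_bp


def _make_record(aid, sire, dam, sex, year) -> PedigreeRecord:
    return PedigreeRecord(aid, sire, dam, sex,
                          _dt.date(int(year), 1, 1))


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Simulate a pedigree under the configured mating design.

    ``mating_design="random"`` breeds a closed population: each generation
    draws a sire and dam uniformly from the previous generation's males and
    females.  A planned design is a list of dicts with ``kind`` in
    ``{"full_sib", "half_sib", "parent_offspring", "closed_population",
    "unrelated"}`` plus ``n_offspring`` (and, for closed populations, the
    population-size fields); planned consanguineous matings are realised
    exactly from fresh founders.  Individual ids encode their group so
    downstream code can stratify cohorts.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[PedigreeRecord] = []
    if cfg.mating_design == "random":
        records += _closed_population(rng, "BG", cfg.n_founders,
                                      cfg.n_generations, cfg.n_per_generation,
                                      cfg.base_year, cfg.years_per_generation)
    else:
        for u, entry in enumerate(cfg.mating_design):
            kind = entry["kind"]
            tag = f"{_KIND_TAGS[kind]}{u}"
            n_off = int(entry.get("n_offspring", 1))
            if kind == "closed_population":
                records += _closed_population(
                    rng, tag,
                    int(entry.get("n_founders", cfg.n_founders)),
                    int(entry.get("n_generations", cfg.n_generations)),
                    int(entry.get("n_per_generation", cfg.n_per_generation)),
                    cfg.base_year, cfg.years_per_generation)
            elif kind == "unrelated":
                y = cfg.base_year
                for i in range(n_off):
                    records.append(_make_record(
                        f"{tag}_X{i:03d}", "", "",
                        "male" if i % 2 == 0 else "female", y))
            else:
                records += _planned_unit(kind, tag, n_off, cfg)
    return Pedigree(records)


_KIND_TAGS = {"full_sib": "FS", "half_sib": "HS", "parent_offspring": "PO",
              "closed_population": "CP", "unrelated": "UN"}


def _closed_population(rng, tag, n_founders, n_generations, n_per_gen,
                       base_year, years_per_gen) -> list[PedigreeRecord]:
    records = []
    males, females = [], []
    for i in range(n_founders):
        sex = "male" if i % 2 == 0 else "female"
        aid = f"{tag}_G0_{i:03d}"
        records.append(_make_record(aid, "", "", sex, base_year))
        (males if sex == "male" else females).append(aid)
    for g in range(1, n_generations + 1):
        year = base_year + g * years_per_gen
        new_m, new_f = [], []
        for i in range(n_per_gen):
            sire = males[rng.integers(len(males))]
            dam = females[rng.integers(len(females))]
            sex = "male" if rng.random() < 0.5 else "female"
            aid = f"{tag}_G{g}_{i:03d}"
            records.append(_make_record(aid, sire, dam, sex, year))
            (new_m if sex == "male" else new_f).append(aid)
        # keep the population closed: next generation breeds from this one,
        # falling back to the previous one if a sex is absent
        males = new_m or males
        females = new_f or females
    return records


def _planned_unit(kind: str, tag: str, n_off: int, cfg: SimConfig
                  ) -> list[PedigreeRecord]:
    y0, dy = cfg.base_year, cfg.years_per_generation
    r: list[PedigreeRecord] = []
    if kind == "full_sib":
        r.append(_make_record(f"{tag}_F0", "", "", "male", y0))
        r.append(_make_record(f"{tag}_F1", "", "", "female", y0))
        r.append(_make_record(f"{tag}_S", f"{tag}_F0", f"{tag}_F1", "male", y0 + dy))
        r.append(_make_record(f"{tag}_D", f"{tag}_F0", f"{tag}_F1", "female", y0 + dy))
        for i in range(n_off):
            r.append(_make_record(f"{tag}_O{i:03d}", f"{tag}_S", f"{tag}_D",
                                  "male" if i % 2 == 0 else "female", y0 + 2 * dy))
    elif kind == "half_sib":
        r.append(_make_record(f"{tag}_F0", "", "", "male", y0))
        r.append(_make_record(f"{tag}_F1", "", "", "female", y0))
        r.append(_make_record(f"{tag}_F2", "", "", "female", y0))
        r.append(_make_record(f"{tag}_S", f"{tag}_F0", f"{tag}_F1", "male", y0 + dy))
        r.append(_make_record(f"{tag}_D", f"{tag}_F0", f"{tag}_F2", "female", y0 + dy))
        for i in range(n_off):
            r.append(_make_record(f"{tag}_O{i:03d}", f"{tag}_S", f"{tag}_D",
                                  "male" if i % 2 == 0 else "female", y0 + 2 * dy))
    elif kind == "parent_offspring":
        r.append(_make_record(f"{tag}_F0", "", "", "male", y0))
        r.append(_make_record(f"{tag}_F1", "", "", "female", y0))
        r.append(_make_record(f"{tag}_D", f"{tag}_F0", f"{tag}_F1", "female", y0 + dy))
        for i in range(n_off):
            r.append(_make_record(f"{tag}_O{i:03d}", f"{tag}_F0", f"{tag}_D",
                                  "male" if i % 2 == 0 else "female", y0 + 2 * dy))
    else:  # pragma: no cover - guarded by caller
        raise ValueError(f"unknown planned mating kind {kind!r}")
    return r


def group_of(individual_id: str) -> str:
    """Cohort group encoded in a simulated id (text before the first '_')."""
    return individual_id.split("_", 1)[0]


# ---------------------------------------------------------------------------
# gene dropping

def _meiosis(rng, hap_a, hap_b, chrom_len, bp_per_morgan, new_id):
    """One gamete: recombine two parental mosaics, prepend the gamete's own
    haplotype-copy id to every inherited lineage chain."""
    length_morgan = chrom_len / bp_per_morgan
    n_x = rng.poisson(length_morgan)
    cuts = np.sort(rng.integers(1, chrom_len, size=n_x)) if n_x else np.array([], int)
    source = int(rng.integers(2))
    haps = (hap_a, hap_b)
    out = []
    start = 0
    bounds = list(cuts) + [chrom_len]
    for end in bounds:
        if end > start:
            for s, e, chain in haps[source]:
                lo, hi = max(s, start), min(e, end)
                if lo < hi:
                    out.append((lo, hi, (new_id,) + chain))
        source ^= 1
        start = end
    return out


def gene_drop(ped: Pedigree, cfg: SimConfig,
              rng: np.random.Generator | None = None
              ) -> tuple[GenotypeMatrix, MarkerMap, TruthSet]:
    """Drop labelled founder haplotypes through the pedigree.

    Returns genotypes (with error/missingness applied), the marker map, and
    the :class:`TruthSet` recorded before noise.  Marker positions are
    evenly spaced; founder reference-allele frequencies are drawn once per
    marker with minor-allele frequency uniform on [maf_min, 0.5].
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    ids = ped.ids
    n_chrom, clen = cfg.n_chromosomes, cfg.chrom_length_bp
    nsnp = cfg.n_snps_per_chrom
    genome_bp = n_chrom * clen

    # marker map: even spacing, strictly increasing
    step = clen // (nsnp + 1)
    pos = (np.arange(1, nsnp + 1) * step).astype(np.int64)
    frames = [pd.DataFrame({"chrom": str(c + 1),
                            "snp_id": [f"snp{c + 1}_{j}" for j in range(nsnp)],
                            "bp": pos}) for c in range(n_chrom)]
    mmap = MarkerMap(pd.concat(frames, ignore_index=True))

    maf = rng.uniform(cfg.maf_min, 0.5, size=n_chrom * nsnp)
    flip = rng.random(n_chrom * nsnp) < 0.5
    founder_freqs = np.where(flip, 1.0 - maf, maf)

    founders = set(ped.founders())
    hap_counter = 0
    founder_hap_alleles: dict[int, np.ndarray] = {}
    # haps[individual] = per-chromosome [paternal_mosaic, maternal_mosaic]
    haps: dict[str, list[list[list[tuple]]]] = {}

    for rec in ped.records:
        aid = rec.animal_id
        if aid in founders:
            per_chrom = []
            for c in range(n_chrom):
                pair = []
                for _ in range(2):
                    h = hap_counter
                    hap_counter += 1
                    freq = founder_freqs[c * nsnp:(c + 1) * nsnp]
                    founder_hap_alleles[h] = (
                        rng.random(nsnp) < freq).astype(np.int8)
                    pair.append([(0, clen, (h,))])
                per_chrom.append(pair)
            haps[aid] = per_chrom
        else:
            per_chrom = []
            for c in range(n_chrom):
                pair = []
                for parent in (rec.sire_id, rec.dam_id):
                    if parent not in haps:
                        raise ValueError(
                            f"{aid}: parent {parent!r} missing; gene dropping "
                            "needs a founder-closed pedigree")
                    h = hap_counter
                    hap_counter += 1
                    pa, ma = haps[parent][c]
                    pair.append(_meiosis(rng, pa, ma, clen,
                                         cfg.bp_per_morgan, h))
                per_chrom.append(pair)
            haps[aid] = per_chrom

    # genotypes from founder labels
    values = np.empty((len(ids), n_chrom * nsnp), dtype=np.int8)
    for i, aid in enumerate(ids):
        for c in range(n_chrom):
            dose = np.zeros(nsnp, dtype=np.int8)
            for mosaic in haps[aid][c]:
                for s, e, chain in mosaic:
                    lo = np.searchsorted(pos, s, side="left")
                    hi = np.searchsorted(pos, e - 1, side="right")
                    dose[lo:hi] += founder_hap_alleles[chain[-1]][lo:hi]
            values[i, c * nsnp:(c + 1) * nsnp] = dose

    # truth before noise
    tract_rows = []
    auto_frac = pd.Series(0.0, index=ids)
    for aid in ids:
        total = 0
        for c in range(n_chrom):
            pat, mat = haps[aid][c]
            for s, e, g in _autozygous_cells(pat, mat):
                total += e - s
                tract_rows.append((aid, str(c + 1), s, e, e - s, g))
        auto_frac[aid] = total / genome_bp
    tracts = pd.DataFrame(tract_rows, columns=[
        "individual", "chrom", "start_bp", "end_bp", "length_bp",
        "coalescence_generations"])

    A = build_a_matrix(ped)
    true_f_ped = pd.Series(np.diag(A.values) - 1.0, index=A.ids,
                           name="true_f_ped").reindex(ids)

    # noise applied after truth: symmetric single-allele flips, then missing
    if cfg.genotyping_error > 0:
        err = rng.random(values.shape) < cfg.genotyping_error
        up = rng.random(values.shape) < 0.5
        flipped = np.where(up, values + 1, values - 1)
        flipped = np.clip(flipped, 0, 2)
        # a flip must change the genotype; at the boundaries only one
        # direction exists
        flipped = np.where(flipped == values,
                           np.where(values == 0, 1, 1), flipped)
        values = np.where(err, flipped, values).astype(np.int8)
    if cfg.missing_rate > 0:
        values[rng.random(values.shape) < cfg.missing_rate] = MISSING

    G = GenotypeMatrix(list(ids), list(mmap.frame["snp_id"]), values)
    truth = TruthSet(auto_frac.rename("autozygous_fraction"), tracts,
                     true_f_ped, founder_freqs)
    return G, mmap, truth


def _autozygous_cells(pat, mat):
    """Intersect two lineage mosaics; yield (start, end, g) for cells whose
    founder haplotypes coincide, merging contiguous cells with equal g."""
    cells = []
    for s1, e1, ch1 in pat:
        for s2, e2, ch2 in mat:
            lo, hi = max(s1, s2), min(e1, e2)
            if lo < hi and ch1[-1] == ch2[-1]:
                k = 0
                while (k < len(ch1) and k < len(ch2)
                       and ch1[len(ch1) - 1 - k] == ch2[len(ch2) - 1 - k]):
                    k += 1
                # meioses from the individual to the most recent common
                # haplotype copy, averaged over the two sides of the loop
                g = ((len(ch1) - k) + (len(ch2) - k)) / 2.0
                cells.append((lo, hi, g))
    cells.sort()
    merged = []
    for lo, hi, g in cells:
        if merged and merged[-1][1] == lo and merged[-1][2] == g:
            merged[-1] = (merged[-1][0], hi, g)
        else:
            merged.append((lo, hi, g))
    return merged


def truth_age_profile(truth: TruthSet, bp_per_morgan: float = 1e8
                      ) -> pd.DataFrame:
    """Mean IBD tract length by generations-to-coalescence.

    Under the recombination model, tracts coalescing g generations back
    have expected length ~ 100/(2g) cM, so the profile must decline with g.
    Empty when there is no consanguinity.
    """
    t = truth.tracts
    if t.empty:
        return pd.DataFrame(columns=["n", "mean_length_bp", "mean_length_cm"])
    grp = t.groupby("coalescence_generations")["length_bp"]
    out = pd.DataFrame({
        "n": grp.size(),
        "mean_length_bp": grp.mean(),
        "mean_length_cm": grp.mean() / bp_per_morgan * 100.0,
    })
    out.index.name = "coalescence_generations"
    return out


# ---------------------------------------------------------------------------
# text export

_ALLELES = {0: ("B", "B"), 1: ("A", "B"), 2: ("A", "A"), MISSING: ("0", "0")}


def write_ped_map(G: GenotypeMatrix, M: MarkerMap, prefix) -> tuple[str, str]:
    """Write PED/MAP text files (alleles A/B, missing '0 0'); returns the
    two paths."""
    ped_path, map_path = f"{prefix}.ped", f"{prefix}.map"
    with open(map_path, "w") as fh:
        for _, row in M.frame.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp_id']}\t0\t{row['bp']}\n")
    with open(ped_path, "w") as fh:
        for i, aid in enumerate(G.individual_ids):
            fields = ["FAM", aid, "0", "0", "0", "-9"]
            for g in G.values[i]:
                fields.extend(_ALLELES[int(g)])
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def write_pedigree_csv(ped: Pedigree, path) -> None:
    rows = [(r.animal_id, r.sire_id or "0", r.dam_id or "0", r.sex,
             r.birth_date.isoformat() if r.birth_date else "")
            for r in ped.records]
    pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "birth_date"]
                 ).to_csv(path, index=False)
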