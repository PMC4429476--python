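"""Synthetic cohorts, SNP panels and PLINK text genotype I/O.

Generates the study-shaped inputs for the female-only association scan: an
all-female case/control cohort (one individual per family, mirroring the
unrelatedness constraint of the real analysis), a null SNP panel in
Hardy-Weinberg equilibrium independent of affection status, and a single
embedded protective locus whose carrier frequencies follow the dominant
female-protection model.  Panels follow the discovery-array shape: 451
X SNPs inside X-inactivation-escape regions, 6,955 X SNPs in total, and
a genome-wide autosomal backbone.

Linkage disequilibrium is deliberately not simulated: the hypothesis under
test concerns a single common locus, and independent SNPs are exactly the
null the scan calibrates against.

File formats: PLINK text PED/MAP (phenotype 1 = unaffected / 2 = affected,
sex code 2 = female, missing genotype "0 0", MAP positions 1-based), BED
(0-based half-open) for chromosome X region sets, TSV for cohort tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortTable",
    "SnpPanelSpec",
    "GenotypeMatrix",
    "EmbeddedLocusSpec",
    "DEFAULT_ESCAPE_REGIONS",
    "DEFAULT_Y_HOMOLOGY_REGIONS",
    "simulate_cohort",
    "simulate_null_genotypes",
    "embed_fpe_locus",
    "write_plink_text",
    "read_plink_text",
    "write_bed",
    "read_bed",
    "PlinkParseError",
]

MISSING = np.int8(-1)

#: Synthetic chromosome X annotation (hg19-like coordinates, 0-based
#: half-open).  The Y-homology set is the two pseudoautosomal regions; the
#: escape set is a plausible arrangement concentrated on Xp, totalling
#: ~21.8 Mbp (about 14% of the chromosome).  Both are stand-ins for the
#: real annotation, which is not redistributable here.
DEFAULT_Y_HOMOLOGY_REGIONS = (
    ("X", 60_000, 2_699_520),
    ("X", 154_931_043, 155_260_560),
)
DEFAULT_ESCAPE_REGIONS = (
    ("X", 100_000, 9_500_000),
    ("X", 10_000_000, 16_000_000),
    ("X", 46_000_000, 49_500_000),
    ("X", 152_000_000, 154_900_000),
)

CHROM_X_LENGTH = 155_270_560
_AUTOSOME_LENGTH = 240_000_000


class PlinkParseError(ValueError):
    """Malformed PLINK text input, annotated with the offending line."""


@dataclass(frozen=True)
class SnpPanelSpec:
    """Shape of a simulated SNP panel.

    Defaults mirror the discovery panel: 451 tier-1 X SNPs (inside escape
    regions, outside Y-homology), 6,504 other X SNPs, and an autosomal
    backbone.  MAFs are uniform over ``maf_range`` and genotypes are
    missing independently at ``missing_rate``.
    """

    n_tier1: int = 451
    n_chrx_other: int = 6_504
    n_autosomal: int = 10_000
    maf_range: tuple = (0.03, 0.5)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_tier1, self.n_chrx_other, self.n_autosomal) < 0:
            raise ValueError("SNP counts must be >= 0")
        lo, hi = self.maf_range
        if not 0.0 <= lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 <= low <= high <= 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass(frozen=True)
class EmbeddedLocusSpec:
    """One SNP with status-dependent carrier frequencies of allele 2.

    ``target_case_carrier_freq`` / ``target_control_carrier_freq`` are the
    probabilities that an affected / unaffected female carries at least one
    copy of the protective allele 2; carriers are split heterozygote /
    homozygote by the Hardy-Weinberg conditional at ``allele2_freq``.
    """

    target_case_carrier_freq: float
    target_control_carrier_freq: float
    allele2_freq: float = 0.5
    chromosome: str = "X"
    position: int = 5_000_000  # inside the first escape region
    snp_id: str = "rsFPE"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("target_case_carrier_freq", "target_control_carrier_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.allele2_freq <= 1.0:
            raise ValueError("allele2_freq must lie in (0, 1]")


class CohortTable:
    """Per-individual phenotype records backed by a DataFrame.

    Columns: ``id``, ``family_id``, ``sex`` ("female"/"male"), ``affected``
    (bool), ``srs`` (float, NaN when absent).
    """

    COLUMNS = ["id", "family_id", "sex", "affected", "srs"]

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"cohort table lacks columns {sorted(missing)}")
        if table["id"].duplicated().any():
            raise ValueError("individual ids must be unique")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def affected(self) -> np.ndarray:
        return self.table["affected"].to_numpy(dtype=bool)

    @property
    def ids(self) -> list:
        return self.table["id"].tolist()

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["affected"] = np.where(out["affected"], "affected", "unaffected")
        out.to_csv(path, sep="\t", index=False, float_format="%.3f")

    @classmethod
    def from_tsv(cls, path) -> "CohortTable":
        t = pd.read_csv(path, sep="\t", dtype={"id": str, "family_id": str})
        t["affected"] = t["affected"].astype(str).str.lower().eq("affected")
        if "srs" not in t.columns:
            t["srs"] = np.nan
        return cls(t)


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic SNPs, as allele-1 dosage {0, 1, 2} or -1.

    ``snps`` carries per-SNP metadata: ``snp_id``, ``chrom``, ``pos``
    (1-based), ``allele1``, ``allele2``.  Positions are strictly increasing
    within a chromosome.
    """

    dosage: np.ndarray
    snps: pd.DataFrame
    sample_ids: list

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x SNPs)")
        if self.dosage.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.dosage, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2} or -1 for missing")
        for chrom, sub in self.snps.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def missing_rate_per_snp(self) -> np.ndarray:
        return np.mean(self.dosage == MISSING, axis=0)

    def call_rate_per_sample(self) -> np.ndarray:
        return 1.0 - np.mean(self.dosage == MISSING, axis=1)

    def allele1_freq(self) -> np.ndarray:
        """Per-SNP allele-1 frequency over non-missing genotypes."""
        d = self.dosage
        obs = d != MISSING
        counts = np.where(obs, d, 0).sum(axis=0)
        denom = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(denom > 0, counts / denom, np.nan)

    def maf(self) -> np.ndarray:
        f = self.allele1_freq()
        return np.minimum(f, 1.0 - f)

    def subset(self, sample_mask=None, snp_mask=None) -> "GenotypeMatrix":
        d = self.dosage
        sids = self.sample_ids
        snps = self.snps
        if sample_mask is not None:
            d = d[sample_mask]
            sids = [s for s, k in zip(self.sample_ids, sample_mask) if k]
        if snp_mask is not None:
            d = d[:, snp_mask]
            snps = snps.loc[snp_mask].reset_index(drop=True)
        return GenotypeMatrix(d.copy(), snps.copy(), list(sids))


def simulate_cohort(
    n_affected: int,
    n_unaffected: int,
    seed: int = 0,
    with_srs: bool = True,
    affected_srs: tuple = (105.0, 20.0),
    unaffected_srs: tuple = (15.0, 20.0),
) -> CohortTable:
    """All-female case/control cohort, one individual per family.

    Optional SRS scores are drawn from status-specific normals whose means
    sit 4.5 SD apart, matching the bimodal multiplex-female picture; the
    defaults give the 208/151 discovery shape with ``(208, 151)``.
    """
    if n_affected < 0 or n_unaffected < 0:
        raise ValueError("cohort counts must be >= 0")
    n = n_affected + n_unaffected
    rng = np.random.default_rng(seed)
    affected = np.zeros(n, dtype=bool)
    affected[:n_affected] = True
    srs = np.full(n, np.nan)
    if with_srs and n:
        srs[affected] = rng.normal(*affected_srs, size=n_affected)
        srs[~affected] = rng.normal(*unaffected_srs, size=n_unaffected)
    table = pd.DataFrame(
        {
            "id": [f"I{i:05d}" for i in range(n)],
            "family_id": [f"F{i:05d}" for i in range(n)],
            "sex": "female",
            "affected": affected,
            "srs": srs,
        }
    )
    return CohortTable(table)


def _panel_metadata(panel: SnpPanelSpec, rng: np.random.Generator) -> pd.DataFrame:
    """SNP positions/ids for the three panel strata, sorted by chromosome."""
    frames = []
    esc = [(s, e) for _, s, e in DEFAULT_ESCAPE_REGIONS]
    yhom = [(s, e) for _, s, e in DEFAULT_Y_HOMOLOGY_REGIONS]

    def in_any(pos, regions):
        return np.any([(pos >= s) & (pos < e) for s, e in regions], axis=0)

    if panel.n_tier1:
        # rejection-sample escape-region positions outside Y homology
        pos = np.empty(0, dtype=np.int64)
        widths = np.array([e - s for s, e in esc], dtype=float)
        while pos.size < panel.n_tier1:
            need = panel.n_tier1 - pos.size
            reg = rng.choice(len(esc), size=2 * need + 8, p=widths / widths.sum())
            cand = np.array(
                [rng.integers(esc[r][0], esc[r][1]) for r in reg], dtype=np.int64
            )
            cand = cand[~in_any(cand, yhom)]
            pos = np.unique(np.concatenate([pos, cand]))
        pos = np.sort(rng.choice(pos, size=panel.n_tier1, replace=False))
        frames.append(pd.DataFrame({"chrom": "X", "pos0": pos}))
    if panel.n_chrx_other:
        pos = np.empty(0, dtype=np.int64)
        while pos.size < panel.n_chrx_other:
            cand = rng.integers(0, CHROM_X_LENGTH, size=2 * (panel.n_chrx_other - pos.size) + 8)
            cand = cand[~in_any(cand, esc)]
            pos = np.unique(np.concatenate([pos, cand]))
        pos = np.sort(rng.choice(pos, size=panel.n_chrx_other, replace=False))
        frames.append(pd.DataFrame({"chrom": "X", "pos0": pos}))
    if panel.n_autosomal:
        n_per = np.bincount(
            rng.integers(0, 22, size=panel.n_autosomal), minlength=22
        )
        for c in range(22):
            if not n_per[c]:
                continue
            pos = np.sort(
                rng.choice(_AUTOSOME_LENGTH, size=n_per[c], replace=False)
            ).astype(np.int64)
            frames.append(pd.DataFrame({"chrom": str(c + 1), "pos0": pos}))
    meta = pd.concat(frames, ignore_index=True)
    meta = meta.sort_values(["chrom", "pos0"], kind="stable").reset_index(drop=True)
    meta = meta.drop_duplicates(["chrom", "pos0"]).reset_index(drop=True)
    alleles = rng.choice(["A", "C", "G", "T"], size=(len(meta), 2))
    same = alleles[:, 0] == alleles[:, 1]
    alleles[same, 1] = np.where(alleles[same, 0] == "A", "G", "A")
    meta["pos"] = meta["pos0"] + 1  # 1-based for MAP/reports
    meta["snp_id"] = [f"rs{70000 + i}" for i in range(len(meta))]
    meta["allele1"] = alleles[:, 0]
    meta["allele2"] = alleles[:, 1]
    return meta[["snp_id", "chrom", "pos", "allele1", "allele2"]]


def simulate_null_genotypes(panel: SnpPanelSpec, cohort: CohortTable) -> GenotypeMatrix:
    """Status-independent Hardy-Weinberg genotypes for the cohort.

    Per SNP a MAF is drawn from the panel's range, allele 1 is the major
    allele, and female diploid genotypes follow HW proportions; entries go
    missing independently at the panel's ``missing_rate``.
    """
    rng = np.random.default_rng(panel.seed)
    meta = _panel_metadata(panel, rng)
    n_ind, n_snp = len(cohort), len(meta)
    maf = rng.uniform(*panel.maf_range, size=n_snp)
    p2 = maf  # allele 2 is the minor allele
    u = rng.random((n_ind, n_snp))
    hom2 = p2 * p2
    het = 2.0 * p2 * (1.0 - p2)
    # dosage of allele 1: hom2 -> 0, het -> 1, else 2
    dosage = np.where(u < hom2, 0, np.where(u < hom2 + het, 1, 2)).astype(np.int8)
    if panel.missing_rate > 0:
        dosage[rng.random((n_ind, n_snp)) < panel.missing_rate] = MISSING
    return GenotypeMatrix(dosage, meta, cohort.ids)


def embed_fpe_locus(
    genotypes: GenotypeMatrix, cohort: CohortTable, spec: EmbeddedLocusSpec
) -> GenotypeMatrix:
    """Insert the protective locus with status-dependent carrier rates.

    Carrier status of allele 2 is Bernoulli per status group; carriers are
    heterozygous with probability ``2(1-q)/(2-q)`` and homozygous otherwise
    (the HW conditional at allele-2 frequency q).  Allele 1 remains the
    risk allele, so affected females have the higher allele-1 dosage.

    Raises
    ------
    ValueError
        If the target position is already occupied on that chromosome.
    """
    rng = np.random.default_rng(spec.seed)
    snps = genotypes.snps
    pos1 = spec.position  # 1-based, like all per-SNP metadata
    occupied = (
        (snps["chrom"] == spec.chromosome) & (snps["pos"] == pos1)
    ).any()
    if occupied:
        raise ValueError(
            f"position {spec.chromosome}:{pos1} already occupied in the panel"
        )
    affected = cohort.affected
    carrier_p = np.where(
        affected, spec.target_case_carrier_freq, spec.target_control_carrier_freq
    )
    carrier = rng.random(len(cohort)) < carrier_p
    q = spec.allele2_freq
    p_het = 2.0 * (1.0 - q) / (2.0 - q)
    het = rng.random(len(cohort)) < p_het
    dosage = np.full(len(cohort), 2, dtype=np.int8)  # non-carriers: hom allele 1
    dosage[carrier & het] = 1
    dosage[carrier & ~het] = 0
    row = pd.DataFrame(
        {
            "snp_id": [spec.snp_id],
            "chrom": [spec.chromosome],
            "pos": [pos1],
            "allele1": ["A"],
            "allele2": ["G"],
        }
    )
    new_snps = pd.concat([snps, row], ignore_index=True)
    order = new_snps.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    new_dosage = np.concatenate([genotypes.dosage, dosage[:, None]], axis=1)[:, order]
    return GenotypeMatrix(
        new_dosage, new_snps.iloc[order].reset_index(drop=True), genotypes.sample_ids
    )


def write_plink_text(
    genotypes: GenotypeMatrix, cohort: CohortTable, path_prefix
) -> tuple:
    """Write PED/MAP text files; returns the two paths."""
    prefix = Path(path_prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    snps = genotypes.snps
    with open(map_path, "w") as fh:
        for r in snps.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.snp_id}\t0\t{r.pos}\n")

    a1 = snps["allele1"].to_numpy()
    a2 = snps["allele2"].to_numpy()
    table = cohort.table
    sex_code = np.where(table["sex"].to_numpy() == "female", 2, 1)
    phe_code = np.where(table["affected"].to_numpy(), 2, 1)
    with open(ped_path, "w") as fh:
        for i in range(genotypes.n_individuals):
            d = genotypes.dosage[i]
            first = np.where(d >= 1, a1, a2)
            second = np.where(d == 2, a1, a2)
            first = np.where(d == MISSING, "0", first)
            second = np.where(d == MISSING, "0", second)
            geno = " ".join(f + " " + s for f, s in zip(first, second))
            row = table.iloc[i]
            fh.write(
                f"{row['family_id']} {row['id']} 0 0 {sex_code[i]} "
                f"{phe_code[i]} {geno}\n"
            )
    return ped_path, map_path


def read_plink_text(path_prefix) -> tuple:
    """Read PED/MAP text files back into (GenotypeMatrix, CohortTable).

    Raises
    ------
    PlinkParseError
        On malformed line lengths, unknown allele symbols or duplicate SNP
        ids, with 1-based line numbers.
    """
    prefix = Path(path_prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")

    rows = []
    seen = set()
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise PlinkParseError(
                    f"{map_path}:{ln}: expected 4 columns, got {len(parts)}"
                )
            chrom, snp_id, _, pos = parts
            if snp_id in seen:
                raise PlinkParseError(f"{map_path}:{ln}: duplicate snp id {snp_id!r}")
            seen.add(snp_id)
            rows.append((snp_id, chrom, int(pos)))
    meta = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])
    n_snp = len(meta)

    ids, fams, sexes, phes = [], [], [], []
    geno_rows = []
    allele_obs: list = [dict() for _ in range(n_snp)]
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snp:
                raise PlinkParseError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_snp} columns, "
                    f"got {len(parts)}"
                )
            fam, ind, _pat, _mat, sex, phe = parts[:6]
            fams.append(fam)
            ids.append(ind)
            sexes.append("female" if sex == "2" else "male")
            phes.append(phe == "2")
            alleles = parts[6:]
            for j in range(n_snp):
                for a in (alleles[2 * j], alleles[2 * j + 1]):
                    if a == "0":
                        continue
                    if a not in "ACGT" or len(a) != 1:
                        raise PlinkParseError(
                            f"{ped_path}:{ln}: unknown allele symbol {a!r} "
                            f"at snp {meta['snp_id'][j]}"
                        )
                    allele_obs[j][a] = allele_obs[j].get(a, 0) + 1
            geno_rows.append(alleles)

    # fix allele labels: allele1 = first-observed symbol per SNP (two max)
    a1l, a2l = [], []
    for j in range(n_snp):
        obs = list(allele_obs[j].keys())
        if len(obs) > 2:
            raise PlinkParseError(
                f"{ped_path}: snp {meta['snp_id'][j]} shows >2 alleles {obs}"
            )
        a1l.append(obs[0] if obs else "A")
        a2l.append(obs[1] if len(obs) > 1 else ("G" if a1l[-1] != "G" else "A"))
    meta["allele1"] = a1l
    meta["allele2"] = a2l

    n_ind = len(ids)
    dosage = np.full((n_ind, n_snp), MISSING, dtype=np.int8)
    for i, alleles in enumerate(geno_rows):
        arr = np.array(alleles).reshape(n_snp, 2)
        miss = (arr == "0").any(axis=1)
        d = (arr == np.array(a1l)[:, None]).sum(axis=1).astype(np.int8)
        d[miss] = MISSING
        dosage[i] = d

    cohort = CohortTable(
        pd.DataFrame(
            {
                "id": ids,
                "family_id": fams,
                "sex": sexes,
                "affected": phes,
                "srs": np.nan,
            }
        )
    )
    return GenotypeMatrix(dosage, meta, ids), cohort


def write_bed(regions, path) -> None:
    """Write (chrom, start, end) triples as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed(path) -> list:
    """Read a BED file into (chrom, start, end) triples (0-based half-open)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
            start, end = int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{ln}: empty or inverted interval")
            out.append((parts[0], start, end))
    return out
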