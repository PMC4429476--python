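"""Quality control, tier selection and female-only association testing.

Implements the scan's data-cleaning thresholds (sample call rate >= 0.95,
per-SNP missingness <= 0.1, MAF >= 0.03, Hardy-Weinberg exact p >= 1e-4, tested in unaffected individuals),
the three SNP tiers (1: chromosome X SNPs inside X-inactivation-escape
regions and outside Y-homology; 2: all of chromosome X; 3: genome-wide),
dominant and additive association tests with Bonferroni correction over
the SNPs analysed in the tier, SRS-based phenotype redefinitions, the
genomic-inflation factor and top-hit reporting.

The dominant test compares carriers of allele 1 (dosage >= 1) against
non-carriers with a two-sided Fisher exact test (a chi-square variant is
available); the odds ratio uses the Haldane-Anscombe 0.5 correction when a
cell is empty.  The additive test is the Cochran-Armitage trend test on
dosages with weights (0, 1, 2).  Coordinates are 0-based half-open
internally (BED convention); SNP positions are 1-based in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, CohortTable, GenotypeMatrix

__all__ = [
    "QcThresholds",
    "TierSpec",
    "QcReport",
    "hwe_exact_test",
    "apply_qc",
    "select_tier",
    "dominant_test",
    "additive_test",
    "bonferroni_correct",
    "run_association",
    "redefine_status_by_srs",
    "genomic_inflation",
    "top_k_report",
]


@dataclass(frozen=True)
class QcThresholds:
    maf_min: float = 0.03
    snp_missing_max: float = 0.1
    sample_call_rate_min: float = 0.95
    hwe_p_min: float = 1e-4

    def __post_init__(self) -> None:
        for name in (
            "maf_min",
            "snp_missing_max",
            "sample_call_rate_min",
            "hwe_p_min",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class TierSpec:
    """Tier definition with X region sets (0-based half-open intervals)."""

    tier: int
    escape_regions: tuple = ()
    y_homology_regions: tuple = ()
    x_chrom: str = "X"

    def __post_init__(self) -> None:
        if self.tier not in (1, 2, 3):
            raise ValueError("tier must be 1, 2 or 3")
        for regions in (self.escape_regions, self.y_homology_regions):
            for chrom, start, end in regions:
                if start < 0 or start >= end:
                    raise ValueError(
                        f"malformed interval {chrom}:{start}-{end}"
                    )


@dataclass
class QcReport:
    n_samples_in: int = 0
    n_snps_in: int = 0
    samples_removed_call_rate: int = 0
    snps_removed_missingness: int = 0
    snps_removed_maf: int = 0
    snps_removed_hwe: int = 0

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - self.samples_removed_call_rate

    @property
    def n_snps_out(self) -> int:
        return (
            self.n_snps_in
            - self.snps_removed_missingness
            - self.snps_removed_maf
            - self.snps_removed_hwe
        )


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts (with matching parity) no more probable than
    the observed one.  Monomorphic SNPs return 1.0.

    Raises
    ------
    ValueError
        On negative counts or an empty table (all genotypes missing).
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be >= 0")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("HWE test undefined: no observed genotypes")
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    if n_rare == 0:
        return 1.0
    probs = _hwe_het_distribution(n, n_rare)
    idx = n_het // 2  # heterozygote counts share the parity of n_rare
    p_obs = probs[idx]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def _hwe_het_distribution(n: int, n_rare: int) -> np.ndarray:
    """Probabilities of each possible heterozygote count given allele counts.

    Uses the standard recurrence
    P(h-2) / P(h) = h (h-1) / (4 (hom1+1) (hom2+1)) walked from the mode,
    then normalises.  Entry ``i`` is heterozygote count ``parity + 2 i``.
    """
    parity = n_rare % 2
    h_max = min(n_rare, 2 * n - n_rare)
    hs = np.arange(parity, h_max + 1, 2)
    logp = np.zeros(len(hs))
    for i in range(1, len(hs)):
        h = hs[i]
        rare_homs = (n_rare - h) / 2.0
        common_homs = n - h - rare_homs
        # P(h) / P(h-2) = 4 rare_homs_prev common_homs_prev / (h (h-1))
        logp[i] = logp[i - 1] + math.log(
            4.0 * (rare_homs + 1.0) * (common_homs + 1.0) / (h * (h - 1.0))
        )
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


def apply_qc(
    genotypes: GenotypeMatrix,
    thresholds: QcThresholds = QcThresholds(),
    affected=None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Filter samples then SNPs (missingness, MAF, HWE), in that order.

    When ``affected`` (boolean per sample) is given, the HWE filter is
    computed on unaffected individuals only — the conventional choice for
    case/control data, since a genuinely associated locus departs from HWE
    in the pooled sample.  Without it, all individuals are pooled.  An
    empty result is returned as an empty matrix together with the report;
    the caller decides whether that is an error.
    """
    report = QcReport(n_samples_in=genotypes.n_individuals, n_snps_in=genotypes.n_snps)
    keep_s = genotypes.call_rate_per_sample() >= thresholds.sample_call_rate_min
    report.samples_removed_call_rate = int((~keep_s).sum())
    g = genotypes.subset(sample_mask=keep_s) if not keep_s.all() else genotypes
    if affected is not None:
        affected = np.asarray(affected, dtype=bool)[keep_s]

    miss_ok = g.missing_rate_per_snp() <= thresholds.snp_missing_max
    report.snps_removed_missingness = int((~miss_ok).sum())

    maf = g.maf()
    maf_ok = np.where(np.isnan(maf), False, maf >= thresholds.maf_min) | ~miss_ok
    maf_ok &= miss_ok  # attribute each SNP to the first failed criterion
    report.snps_removed_maf = int((miss_ok & ~maf_ok).sum())

    keep = miss_ok & maf_ok
    hwe_fail = np.zeros(g.n_snps, dtype=bool)
    d = g.dosage if affected is None else g.dosage[~affected]
    for j in np.flatnonzero(keep):
        col = d[:, j]
        n2 = int((col == 0).sum())  # hom allele 2
        n_het = int((col == 1).sum())
        n1 = int((col == 2).sum())  # hom allele 1
        if n1 + n_het + n2 == 0:
            continue
        if hwe_exact_test(n1, n_het, n2) < thresholds.hwe_p_min:
            hwe_fail[j] = True
    report.snps_removed_hwe = int(hwe_fail.sum())
    keep &= ~hwe_fail
    return g.subset(snp_mask=keep), report


def _in_regions(chroms, pos0, regions) -> np.ndarray:
    """Vector membership of 0-based positions in (chrom, start, end) regions."""
    out = np.zeros(len(pos0), dtype=bool)
    for chrom, start, end in regions:
        out |= (chroms == chrom) & (pos0 >= start) & (pos0 < end)
    return out


def select_tier(snps: pd.DataFrame, spec: TierSpec) -> np.ndarray:
    """Boolean mask of SNPs belonging to the requested tier.

    Tier 1: X SNPs inside escape regions and outside Y-homology regions;
    tier 2: all X SNPs; tier 3: every SNP.  SNP ``pos`` is 1-based and is
    converted to the 0-based interval convention internally.
    """
    chroms = snps["chrom"].to_numpy()
    pos0 = snps["pos"].to_numpy() - 1
    if spec.tier == 3:
        return np.ones(len(snps), dtype=bool)
    on_x = chroms == spec.x_chrom
    if spec.tier == 2:
        return on_x
    mask = on_x & _in_regions(chroms, pos0, spec.escape_regions)
    mask &= ~_in_regions(chroms, pos0, spec.y_homology_regions)
    return mask


def _dominant_table(dosage_col, affected) -> tuple:
    obs = dosage_col != MISSING
    carrier = dosage_col >= 1
    a = int(np.sum(obs & affected & carrier))
    b = int(np.sum(obs & affected & ~carrier))
    c = int(np.sum(obs & ~affected & carrier))
    d = int(np.sum(obs & ~affected & ~carrier))
    return a, b, c, d


def _group_allele1_freq(dosage_col, mask) -> float:
    obs = (dosage_col != MISSING) & mask
    denom = 2.0 * obs.sum()
    return float(dosage_col[obs].sum() / denom) if denom else float("nan")


def dominant_test(
    dosage_col: np.ndarray,
    affected: np.ndarray,
    method: str = "fisher",
) -> dict:
    """Carrier-vs-noncarrier 2x2 association test for one SNP.

    Returns the group allele-1 frequencies (percent), the carrier odds
    ratio (Haldane-Anscombe corrected when a cell is empty) and the
    two-sided p-value.

    Raises
    ------
    ValueError
        If either status group has no observed genotype.
    """
    a, b, c, d = _dominant_table(dosage_col, affected)
    if a + b == 0 or c + d == 0:
        raise ValueError("a status group has no observed genotypes")
    if method == "fisher":
        p = float(stats.fisher_exact([[a, b], [c, d]])[1])
    elif method == "chi2":
        if (a + b) * (c + d) * (a + c) * (b + d) == 0:
            p = 1.0
        else:
            p = float(stats.chi2_contingency([[a, b], [c, d]], correction=False)[1])
    else:
        raise ValueError(f"unknown method {method!r}")
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return {
        "aff_freq1_pct": 100.0 * _group_allele1_freq(dosage_col, affected),
        "unaff_freq1_pct": 100.0 * _group_allele1_freq(dosage_col, ~affected),
        "OR": float(orr),
        "p": p,
        "model": "dominant",
    }


def additive_test(dosage_col: np.ndarray, affected: np.ndarray) -> dict:
    """Cochran-Armitage trend test on dosages with weights (0, 1, 2).

    Reports the allelic odds ratio (with 0.5 correction on empty allele
    cells) alongside the two-sided trend p-value.
    """
    obs = dosage_col != MISSING
    if not (obs & affected).any() or not (obs & ~affected).any():
        raise ValueError("a status group has no observed genotypes")
    d = dosage_col[obs]
    aff = affected[obs]
    w = np.array([0.0, 1.0, 2.0])
    r = np.array([np.sum(aff & (d == g)) for g in (0, 1, 2)], dtype=float)
    s = np.array([np.sum(~aff & (d == g)) for g in (0, 1, 2)], dtype=float)
    n_i = r + s
    R, S = r.sum(), s.sum()
    N = R + S
    T = float(np.sum(w * (S * r - R * s)))
    var = (R * S / N) * (
        float(np.sum(w**2 * n_i)) - float(np.sum(w * n_i)) ** 2 / N
    )
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = T / math.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    # allelic odds ratio
    a = float(np.sum(d[aff]))
    b = 2.0 * aff.sum() - a
    c = float(np.sum(d[~aff]))
    e = 2.0 * (~aff).sum() - c
    if min(a, b, c, e) == 0:
        orr = ((a + 0.5) * (e + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * e) / (b * c)
    return {
        "aff_freq1_pct": 100.0 * _group_allele1_freq(dosage_col, affected),
        "unaff_freq1_pct": 100.0 * _group_allele1_freq(dosage_col, ~affected),
        "OR": float(orr),
        "p": p,
        "model": "additive",
    }


def bonferroni_correct(p: float, m: int) -> float:
    """min(1, p * m)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)


def run_association(
    genotypes: GenotypeMatrix,
    cohort: CohortTable,
    tier_spec: TierSpec,
    model: str = "dominant",
    method: str = "fisher",
) -> pd.DataFrame:
    """Per-SNP association over one tier with Bonferroni correction.

    The correction multiplier is the number of SNPs analysed in the tier
    (SNPs skipped for lack of data are excluded from it).  Returns a
    DataFrame with snp metadata, tier, model, group frequencies, OR,
    nominal and corrected p, sorted by nominal p.
    """
    if list(genotypes.sample_ids) != cohort.ids:
        raise ValueError("genotype matrix and cohort are not aligned")
    mask = select_tier(genotypes.snps, tier_spec)
    affected = cohort.affected
    rows = []
    skipped = []
    for j in np.flatnonzero(mask):
        col = genotypes.dosage[:, j]
        try:
            if model == "dominant":
                res = dominant_test(col, affected, method=method)
            elif model == "additive":
                res = additive_test(col, affected)
            else:
                raise ValueError(f"unknown model {model!r}")
        except ValueError as exc:
            skipped.append((genotypes.snps["snp_id"].iloc[j], str(exc)))
            continue
        meta = genotypes.snps.iloc[j]
        rows.append(
            {
                "snp": meta["snp_id"],
                "chrom": meta["chrom"],
                "pos": int(meta["pos"]),
                "tier": tier_spec.tier,
                **res,
            }
        )
    out = pd.DataFrame(rows)
    m = len(out)
    if m:
        out["p_corrected"] = np.minimum(1.0, out["p"] * m)
        out = out.sort_values(["p", "snp"], kind="stable").reset_index(drop=True)
    out.attrs["n_tests"] = m
    out.attrs["skipped"] = skipped
    return out


def redefine_status_by_srs(
    cohort: CohortTable,
    mode: str,
    cutoff: float | None = None,
    quantile: float = 0.25,
) -> CohortTable:
    """Case/control status from SRS scores instead of diagnosis.

    ``mode="threshold"``: affected = SRS >= cutoff.  ``mode="extremes"``:
    keep only the top ``quantile`` fraction of the affected SRS
    distribution and the bottom fraction of the unaffected one, dropping
    the middle.  Individuals without an SRS score are dropped; the number
    is reported in ``table.attrs["n_dropped_missing_srs"]``.
    """
    t = cohort.table.copy()
    has = t["srs"].notna().to_numpy()
    dropped = int((~has).sum())
    t = t.loc[has].reset_index(drop=True)
    if mode == "threshold":
        if cutoff is None:
            raise ValueError("threshold mode needs a cutoff")
        t["affected"] = t["srs"] >= cutoff
    elif mode == "extremes":
        if not 0.0 < quantile <= 1.0:
            raise ValueError("quantile must lie in (0, 1]")
        aff = t["affected"].to_numpy(dtype=bool)
        keep = np.zeros(len(t), dtype=bool)
        for group_mask, top in ((aff, True), (~aff, False)):
            idx = np.flatnonzero(group_mask)
            if idx.size == 0:
                continue
            k = max(1, int(round(quantile * idx.size)))
            sub = t.iloc[idx].sort_values(
                ["srs", "id"], ascending=[not top, True], kind="stable"
            )
            keep[sub.index[:k]] = True
        t = t.loc[keep].reset_index(drop=True)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = CohortTable(t)
    out.table.attrs["n_dropped_missing_srs"] = dropped
    return out


def genomic_inflation(p_values) -> float:
    """Genomic-inflation factor lambda.

    Median of the implied 1-df chi-square statistics over the theoretical
    null median (0.4549...).

    Raises
    ------
    ValueError
        For fewer than 100 p-values or values outside (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 100:
        raise ValueError("need >= 100 p-values for a stable lambda")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def top_k_report(results: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """First k rows by nominal p (ties broken by snp id)."""
    if results.empty:
        raise ValueError("empty association results")
    out = results.sort_values(["p", "snp"], kind="stable").head(k)
    return out.reset_index(drop=True)
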