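"""Single-locus dominant female-protection model.

The model underlying the whole package: a common biallelic locus at which
allele 2 protects females from an otherwise highly penetrant liability to an
autism diagnosis.  Protection is dominant (one copy suffices), acts only in
females, and is allowed to fail with probability ``1 - protection_efficacy``.
Females in multiplex families are treated as universally exposed to high risk,
so an exposed female is diagnosed unless she carries a working copy of the
protective allele.

Under these assumptions the male:female incidence ratio attributable to the
protective locus is

    r_fpe = 1 / (1 - e * c),    c = q (2 - q) = P(carrier),

with ``q`` the protective-allele frequency and ``e`` the efficacy.  The share
of the observed sex bias attributed to the locus is controlled by
``fpe_share`` (s): the locus accounts for a factor ``1 + s (r - 1)`` of the
observed ratio ``r``.

Two frequency scales are reported for the hypothetical locus:

* the *risk-genotype* (dominant-test) scale -- the share of each group whose
  genotype carries no working protection.  This is the quantity a dominant
  carrier-vs-noncarrier test compares, and the scale on which the predicted
  case/control contrast (97.0% vs <24.3%, carrier OR >88) is expressed;
* the plain allele-frequency scale from enumerating genotype classes among
  exposed females.

The unaffected-group figure on the risk-genotype scale is an upper *bound*:
it equals the Hardy-Weinberg noncarrier share (1-q)^2 in the limit of
unexposed (general-population-like) controls, and any risk exposure among
controls removes unprotected females into the affected group, depleting the
noncarrier class.  Hence the strict "<" on the control side of the predicted
contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

__all__ = [
    "FpeModelParams",
    "PredictedLocus",
    "InfeasibleModelError",
    "solve_protective_freq",
    "predict_case_control_freqs",
    "ideal_conditions",
    "calibrated_conditions",
    "attenuated_conditions",
    "genotype_class_weights",
    "PRESETS",
    "get_preset",
]


class InfeasibleModelError(ValueError):
    """Raised when no protective-allele frequency in [0, 1] satisfies the model."""


def _check_prob(name: str, x: float) -> None:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {x!r}")


@dataclass(frozen=True)
class FpeModelParams:
    """Parameters of the single-locus dominant protection model.

    Parameters
    ----------
    sex_bias_ratio : float
        Observed male:female incidence ratio (>= 1), e.g. 4.0 or 5.25.
    fpe_share : float
        Fraction of the incidence-ratio excess attributed to the protective
        locus; 1.0 means the locus alone explains the sex bias.
    protective_allele_freq : float
        Population frequency q of the protective allele (allele 2).
    protection_efficacy : float
        Probability that a risk-exposed carrier escapes diagnosis.
    exposed_fraction : float
        Fraction of females exposed to high risk; 1.0 (the default) models
        multiplex-family females.
    inheritance_mode : str
        Only ``"dominant"`` is implemented.
    """

    sex_bias_ratio: float
    fpe_share: float = 1.0
    protective_allele_freq: float = 0.0
    protection_efficacy: float = 1.0
    exposed_fraction: float = 1.0
    inheritance_mode: str = "dominant"

    def __post_init__(self) -> None:
        if self.sex_bias_ratio < 1.0:
            raise ValueError(f"sex_bias_ratio must be >= 1, got {self.sex_bias_ratio}")
        _check_prob("fpe_share", self.fpe_share)
        _check_prob("protective_allele_freq", self.protective_allele_freq)
        _check_prob("protection_efficacy", self.protection_efficacy)
        _check_prob("exposed_fraction", self.exposed_fraction)
        if self.inheritance_mode != "dominant":
            raise NotImplementedError(
                f"inheritance_mode {self.inheritance_mode!r} not implemented"
            )

    @property
    def attributed_ratio(self) -> float:
        """Incidence-ratio factor the locus must account for: 1 + s (r - 1)."""
        return 1.0 + self.fpe_share * (self.sex_bias_ratio - 1.0)

    @property
    def carrier_fraction(self) -> float:
        """Hardy-Weinberg carrier share c = q (2 - q)."""
        q = self.protective_allele_freq
        return q * (2.0 - q)


@dataclass(frozen=True)
class PredictedLocus:
    """Model-predicted case/control contrast at the protective locus.

    Frequencies are percentages.  ``case_allele1_freq`` and
    ``control_allele1_freq_bound`` are on the risk-genotype (dominant-test)
    scale: the share of each group with no working protection.  The control
    figure is an upper bound (population limit), the odds ratio a lower bound.
    The allelic-scale enumeration among exposed females is carried alongside.
    """

    case_allele1_freq: float
    control_allele1_freq_bound: float
    odds_ratio_bound: float
    nominal_p_bound: float
    corrected_p_bound: float
    case_allele1_freq_allelic: float = float("nan")
    control_allele1_freq_allelic: float = float("nan")
    case_classes: dict = field(default_factory=dict)
    control_classes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.case_allele1_freq < self.control_allele1_freq_bound:
            raise ValueError(
                "predicted case risk-allele frequency below the control bound: "
                "allele 2 would not be protective"
            )


def solve_protective_freq(
    sex_bias_ratio: float, fpe_share: float, efficacy: float
) -> float:
    """Solve for the protective-allele frequency q implied by the sex bias.

    Finds q such that partially effective dominant protection reproduces the
    FPE-attributed share of the male:female incidence ratio:
    ``e * q(2-q) = 1 - 1 / (1 + s (r - 1))``.

    Raises
    ------
    InfeasibleModelError
        If the required risk reduction exceeds what the efficacy permits
        (carrier fraction would have to exceed 1).
    """
    if sex_bias_ratio < 1.0:
        raise ValueError(f"sex_bias_ratio must be >= 1, got {sex_bias_ratio}")
    _check_prob("fpe_share", fpe_share)
    _check_prob("efficacy", efficacy)

    r_fpe = 1.0 + fpe_share * (sex_bias_ratio - 1.0)
    reduction = 1.0 - 1.0 / r_fpe  # required e*c
    if reduction == 0.0:
        return 0.0
    if efficacy <= 0.0 or reduction > efficacy:
        raise InfeasibleModelError(
            f"required risk reduction {reduction:.4f} exceeds the bound set by "
            f"protection_efficacy={efficacy}: no q in [0, 1] gives carrier "
            f"fraction {reduction}/{efficacy} <= 1"
        )
    c = reduction / efficacy  # carrier fraction q(2-q)
    return 1.0 - math.sqrt(1.0 - c)


def genotype_class_weights(params: FpeModelParams) -> dict:
    """Joint probabilities of the genotype x outcome classes for exposed females.

    Genotypes AA / Aa / aa (A = risk allele 1, a = protective allele 2) at
    Hardy-Weinberg proportions; exposed noncarriers are diagnosed, carriers
    escape with probability ``protection_efficacy``.  The six weights sum to 1.
    """
    q = params.protective_allele_freq
    e = params.protection_efficacy
    w_aa = (1.0 - q) ** 2  # AA, no protection
    w_het = 2.0 * q * (1.0 - q)
    w_prot = q * q
    return {
        ("AA", "affected"): w_aa,
        ("Aa", "affected"): w_het * (1.0 - e),
        ("aa", "affected"): w_prot * (1.0 - e),
        ("AA", "unaffected"): 0.0,
        ("Aa", "unaffected"): w_het * e,
        ("aa", "unaffected"): w_prot * e,
    }


def predict_case_control_freqs(
    params: FpeModelParams,
    n_cases: int = 208,
    n_controls: int = 151,
    n_tests: int = 451,
) -> PredictedLocus:
    """Predicted group frequencies, odds ratio and significance bounds.

    Enumerates the genotype classes of exposed females under ``params`` and
    derives (a) risk-genotype shares for affected females and the
    population-limit bound for unaffected females, (b) the implied dominant
    carrier odds ratio, (c) allele-1 frequencies on the allelic scale, and
    (d) the Fisher-test p expected at the reference cohort size (defaults:
    the 208-case / 151-control discovery cohort, Bonferroni over 451 tests).
    """
    q = params.protective_allele_freq
    e = params.protection_efficacy
    classes = genotype_class_weights(params)
    total = sum(classes.values())
    p_aff = sum(v for (g, s), v in classes.items() if s == "affected")
    if p_aff <= 0.0:
        raise InfeasibleModelError("model predicts no affected females")

    # risk-genotype (dominant) scale
    case_risk_share = classes[("AA", "affected")] / p_aff
    control_risk_bound = (1.0 - q) ** 2  # population limit, approached from below

    def _odds(p: float) -> float:
        return p / (1.0 - p) if p < 1.0 else math.inf

    ctrl_odds = _odds(control_risk_bound)
    or_bound = math.inf if ctrl_odds == 0 else _odds(case_risk_share) / ctrl_odds

    # allele-frequency scale among exposed females
    aff_alleles = 2.0 * classes[("AA", "affected")] + classes[("Aa", "affected")]
    case_freq1_allelic = aff_alleles / (2.0 * p_aff)
    p_unaff = total - p_aff
    if p_unaff > 0:
        una_alleles = classes[("Aa", "unaffected")]
        control_freq1_allelic = una_alleles / (2.0 * p_unaff)
    else:
        control_freq1_allelic = float("nan")

    # expected-count Fisher p at the reference cohort (dominant 2x2)
    a = int(round(case_risk_share * n_cases))
    c = int(round(control_risk_bound * n_controls))
    table = [[a, n_cases - a], [c, n_controls - c]]
    nominal_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    corrected_p = min(1.0, nominal_p * n_tests)

    return PredictedLocus(
        case_allele1_freq=100.0 * case_risk_share,
        control_allele1_freq_bound=100.0 * control_risk_bound,
        odds_ratio_bound=or_bound,
        nominal_p_bound=nominal_p,
        corrected_p_bound=corrected_p,
        case_allele1_freq_allelic=100.0 * case_freq1_allelic,
        control_allele1_freq_allelic=100.0 * control_freq1_allelic,
        case_classes={g: v / p_aff for (g, s), v in classes.items() if s == "affected"},
        control_classes=(
            {g: v / p_unaff for (g, s), v in classes.items() if s == "unaffected"}
            if p_unaff > 0
            else {}
        ),
    )


def ideal_conditions(sex_bias_ratio: float = 4.0) -> FpeModelParams:
    """Fully attributed, completely effective protection.

    The canonical idealisation: the whole sex bias stems from the locus and
    carriers never convert, so ``(1-q)^2 = 1/ratio``.
    """
    q = solve_protective_freq(sex_bias_ratio, 1.0, 1.0)
    return FpeModelParams(
        sex_bias_ratio=sex_bias_ratio,
        fpe_share=1.0,
        protective_allele_freq=q,
        protection_efficacy=1.0,
    )


def calibrated_conditions(
    sex_bias_ratio: float = 4.0, affected_risk_share: float = 0.97
) -> FpeModelParams:
    """Near-ideal model with a calibrated protection-failure share.

    ``affected_risk_share`` (lambda) is the predicted fraction of affected
    females with the fully unprotected genotype; the complement is the
    "modest deviation from ideal" -- carriers whose protection failed.
    Solving P(affected) = 1/r and the lambda constraint jointly gives
    ``(1-q)^2 = lambda / r`` exactly, hence at the defaults q = 0.50756 and
    efficacy e = 0.99010, reproducing the predicted contrast
    97.0% vs <24.25% with carrier OR 101.
    """
    if not 0.0 < affected_risk_share <= 1.0:
        raise ValueError("affected_risk_share must lie in (0, 1]")
    r = sex_bias_ratio
    if r < 1.0:
        raise ValueError("sex_bias_ratio must be >= 1")
    A = affected_risk_share / r  # (1-q)^2
    if A > 1.0:
        raise InfeasibleModelError("affected_risk_share / ratio exceeds 1")
    q = 1.0 - math.sqrt(A)
    c = q * (2.0 - q)
    e = (1.0 - 1.0 / r) / c if c > 0 else 1.0
    return FpeModelParams(
        sex_bias_ratio=r,
        fpe_share=1.0,
        protective_allele_freq=q,
        protection_efficacy=e,
    )


def attenuated_conditions(
    sex_bias_ratio: float = 5.25, fpe_share: float = 0.5
) -> FpeModelParams:
    """Partial-attribution model: ideal-frequency allele, weakened protection.

    The allele keeps the population frequency hypothesised under ideal
    conditions (``(1-q)^2 = 1/ratio``) but its efficacy is scaled down so the
    locus accounts for only ``1 + s (r - 1)`` of the incidence ratio.  At
    r = 5.25, s = 0.5 this gives q = 0.56356 and e = 0.84; it is the
    decomposition that reproduces the 30%-power mixed-sex GWAS scenario.
    """
    q = solve_protective_freq(sex_bias_ratio, 1.0, 1.0)
    c = q * (2.0 - q)
    r_fpe = 1.0 + fpe_share * (sex_bias_ratio - 1.0)
    e = (1.0 - 1.0 / r_fpe) / c if c > 0 else 1.0
    return FpeModelParams(
        sex_bias_ratio=sex_bias_ratio,
        fpe_share=fpe_share,
        protective_allele_freq=q,
        protection_efficacy=e,
    )


#: Named presets (also shipped as plain-text config, see :mod:`fpescan.config`).
PRESETS = {
    "ideal_4to1": lambda: ideal_conditions(4.0),
    "ideal_5.25to1": lambda: ideal_conditions(5.25),
    "half_fpe_5.25to1": lambda: attenuated_conditions(5.25, 0.5),
    "calibrated_4to1": lambda: calibrated_conditions(4.0, 0.97),
}


def get_preset(name: str) -> FpeModelParams:
    """Return the named model preset.

    ``ideal_4to1`` / ``ideal_5.25to1`` are the fully idealised models,
    ``half_fpe_5.25to1`` attributes half the incidence-ratio excess to the
    locus, and ``calibrated_4to1`` is the near-ideal parameterisation behind
    the predicted 97.0 / <24.3 / >88 case-control contrast.
    """
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
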