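"""Parental-bias statistics and the gender-vs-subspecies classification.

For a profiled feature with normalized maternal/paternal read counts
(R_mat, R_pat), the expected maternal count R_e proportions the total into
the tissue's genome-dosage baseline — 2:1 maternal:paternal in the triploid
endosperm, 1:1 in the embryo.  Significance of the departure from R_e is a
Pearson chi-square with one degree of freedom, reported as -log10 P; a
feature is significant at -log10 P >= 1.3 (P <= 0.05).

A feature is called imprinted only when both reciprocal crosses are
significantly biased toward the same parental GENDER; when the significant
direction instead tracks a fixed subspecies ALLELE (so the parental
direction flips between crosses), the feature is subspecies-biased — an
allelic effect, not imprinting.  Combined evidence across crosses takes the
minimum (least significant) of the two, a conservative AND-combination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import log_ndtr

from .model import (
    A_MOTHER,
    B_MOTHER,
    DISCORDANT,
    LOW_COVERAGE,
    MATERNAL_FRACTION,
    MATERNAL_IMPRINT,
    ONE_CROSS_CANDIDATE,
    PATERNAL_IMPRINT,
    SUBSPECIES_A_BIAS,
    SUBSPECIES_B_BIAS,
    UNBIASED,
)

SIGNIFICANCE_NEGLOG10P = 1.3
MIN_READS = 10
LN10 = np.log(10.0)


def expected_counts(r_total: float, tissue: str) -> tuple[float, float]:
    """Expected (maternal, paternal) counts under the tissue's dosage baseline."""
    if r_total <= 0:
        raise ValueError(f"r_total must be positive, got {r_total}")
    frac = MATERNAL_FRACTION[tissue]
    return frac * r_total, (1.0 - frac) * r_total


def bias_statistic(r_mat: float, r_pat: float) -> tuple[float, float]:
    """Parental expression bias: the maternal and paternal read fractions.

    The "bias" quoted for a call is the fraction of the favoured parent, so
    a fully maternal feature has bias 1.00.
    """
    total = r_mat + r_pat
    if total <= 0:
        raise ValueError("cannot compute bias with zero total reads")
    b_mat = r_mat / total
    return b_mat, 1.0 - b_mat


def neglog10_sf_chi2(chi2: float) -> float:
    """-log10 of the chi-square (df=1) survival function, safe for huge chi2.

    Uses sf = 2 * Phi(-sqrt(chi2)) with the log-space normal CDF, which
    stays finite far beyond where the survival probability underflows.
    """
    if chi2 < 0:
        raise ValueError("chi2 must be non-negative")
    return float(-(np.log(2.0) + log_ndtr(-np.sqrt(chi2))) / LN10)


def chi2_test(r_mat: float, r_pat: float, tissue: str) -> tuple[float, float]:
    """Pearson chi-square (df=1) of observed vs dosage-expected allelic counts."""
    total = r_mat + r_pat
    if total < 1:
        raise ValueError("need at least one read")
    e_mat, e_pat = expected_counts(total, tissue)
    chi2 = (r_mat - e_mat) ** 2 / e_mat + (r_pat - e_pat) ** 2 / e_pat
    # observed == expected gives chi2 == 0 exactly; snap float fuzz (the
    # smallest genuine deviation with integer counts is far above 1e-18)
    if chi2 < 1e-18:
        chi2 = 0.0
    return float(chi2), neglog10_sf_chi2(float(chi2))


@dataclass
class BiasTest:
    """Per-cross allelic bias evidence for one feature."""

    r_mat: int
    r_pat: int
    tissue: str
    cross_direction: str

    def __post_init__(self):
        self.r_total = self.r_mat + self.r_pat
        self.expected_mat = (
            MATERNAL_FRACTION[self.tissue] * self.r_total if self.r_total else 0.0
        )
        if self.r_total > 0:
            self.b_mat, self.b_pat = bias_statistic(self.r_mat, self.r_pat)
            self.chi2, self.neglog10p = chi2_test(self.r_mat, self.r_pat, self.tissue)
        else:
            self.b_mat = self.b_pat = float("nan")
            self.chi2 = self.neglog10p = 0.0

    @property
    def direction(self) -> str:
        """"maternal"/"paternal"/"none": side of the dosage expectation."""
        if self.r_total == 0:
            return "none"
        frac = MATERNAL_FRACTION[self.tissue]
        if self.b_mat > frac:
            return "maternal"
        if self.b_mat < frac:
            return "paternal"
        return "none"

    @property
    def favored_allele(self) -> str:
        """Subspecies allele ("A"/"B") over-represented relative to expectation."""
        maternal_is_a = self.cross_direction == A_MOTHER
        if self.direction == "maternal":
            return "A" if maternal_is_a else "B"
        if self.direction == "paternal":
            return "B" if maternal_is_a else "A"
        return "none"

    def significant(self, threshold: float = SIGNIFICANCE_NEGLOG10P) -> bool:
        return self.neglog10p >= threshold


@dataclass
class ImprintCall:
    """Classification of one feature from both reciprocal crosses."""

    feature_id: str
    call: str
    combined_bias: float
    combined_neglog10p: float
    test_a_mother: BiasTest
    test_b_mother: BiasTest


def classify_feature(
    test_a: BiasTest,
    test_b: BiasTest,
    feature_id: str = "",
    min_reads: int = MIN_READS,
    threshold: float = SIGNIFICANCE_NEGLOG10P,
) -> ImprintCall:
    """Combine the two crosses into an imprinting call.

    Coverage gates first: a feature needs >= `min_reads` normalized reads in
    both crosses to be profiled; with coverage in only one cross, a
    significant result there is flagged as a single-cross candidate (not a
    call).  Profiled features require concordant significance in both
    crosses: same parental gender -> imprint; same subspecies allele (gender
    flips) -> subspecies bias; significant both ways but matching neither
    pattern -> discordant; anything else -> unbiased.
    """
    if test_a.tissue != test_b.tissue:
        raise ValueError("crosses come from different tissues")
    if {test_a.cross_direction, test_b.cross_direction} != {A_MOTHER, B_MOTHER}:
        raise ValueError("need one test per reciprocal cross")
    if test_a.cross_direction == B_MOTHER:
        test_a, test_b = test_b, test_a

    low_a = test_a.r_total < min_reads
    low_b = test_b.r_total < min_reads
    if low_a and low_b:
        call = LOW_COVERAGE
    elif low_a or low_b:
        covered = test_b if low_a else test_a
        call = ONE_CROSS_CANDIDATE if covered.significant(threshold) else LOW_COVERAGE
    else:
        sig_a, sig_b = test_a.significant(threshold), test_b.significant(threshold)
        if sig_a and sig_b:
            if test_a.direction == test_b.direction == "maternal":
                call = MATERNAL_IMPRINT
            elif test_a.direction == test_b.direction == "paternal":
                call = PATERNAL_IMPRINT
            elif test_a.favored_allele == test_b.favored_allele == "A":
                call = SUBSPECIES_A_BIAS
            elif test_a.favored_allele == test_b.favored_allele == "B":
                call = SUBSPECIES_B_BIAS
            else:
                call = DISCORDANT
        else:
            call = UNBIASED

    # Combined evidence: the less significant cross carries the reported
    # bias and -log10 P.
    weaker = min((test_a, test_b), key=lambda t: t.neglog10p)
    bias = _reported_bias(call, weaker)
    return ImprintCall(
        feature_id=feature_id,
        call=call,
        combined_bias=bias,
        combined_neglog10p=weaker.neglog10p,
        test_a_mother=test_a,
        test_b_mother=test_b,
    )


def _reported_bias(call: str, weaker: BiasTest) -> float:
    if weaker.r_total == 0:
        return float("nan")
    if call == MATERNAL_IMPRINT:
        return weaker.b_mat
    if call == PATERNAL_IMPRINT:
        return weaker.b_pat
    if call in (SUBSPECIES_A_BIAS, SUBSPECIES_B_BIAS):
        favored_a = call == SUBSPECIES_A_BIAS
        maternal_is_a = weaker.cross_direction == A_MOTHER
        return weaker.b_mat if favored_a == maternal_is_a else weaker.b_pat
    return max(weaker.b_mat, weaker.b_pat)


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted P-values (supplementary output only)."""
    return sps.false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")
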