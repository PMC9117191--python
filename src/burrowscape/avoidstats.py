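"""Tests for non-random co-occurrence: binomial zone model, AUC, LSD contrasts.

Presence/absence of mole signs on survey plots is modelled by a
binomial GLM (logit link) with the survey zone as the only, categorical,
predictor (reference level BURROW). Because the model is saturated in
one factor, the fitted per-zone probability equals the empirical zone
proportion; the model's value is the inferential machinery around it:

* discrimination is summarised by the area under the ROC curve, computed
  as the tie-corrected rank (Mann-Whitney) statistic over the fitted
  per-plot probabilities;
* pairwise zone differences are tested LSD-style — unadjusted two-sided
  Wald contrasts on the log-odds scale, using the GLM covariance;
* a zone with all-0 or all-1 outcomes (complete separation) makes Wald
  standard errors unusable, so contrasts involving such a zone fall back
  to Fisher's exact test on the 2x2 table and are flagged.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .types import SamplePlot, Zone

__all__ = ["ZoneModelFit", "PairwiseContrast", "fit_zone_model", "fit_zone_counts", "pairwise_lsd", "rank_auc"]


@dataclass
class ZoneModelFit:
    """Fitted binomial zone model.

    ``coefficients`` holds the intercept (log-odds in the reference
    zone) followed by one log-odds-ratio per non-reference zone, in
    ``zones`` order. ``fitted_probability`` maps each zone to its fitted
    presence probability (equal to the empirical proportion for this
    saturated model). ``separated_zones`` lists zones with all-0/all-1
    outcomes whose Wald quantities are unreliable.
    """

    zones: list[Zone]
    reference: Zone
    counts: dict[Zone, tuple[int, int]]  # zone -> (n_present, n_plots)
    coefficients: np.ndarray
    standard_errors: np.ndarray
    covariance: np.ndarray
    fitted_probability: dict[Zone, float]
    auc: float
    n_observations: int
    separated_zones: list[Zone]

    @property
    def separation_flag(self) -> bool:
        return bool(self.separated_zones)


@dataclass
class PairwiseContrast:
    """An unadjusted (LSD) pairwise zone contrast on the log-odds scale."""

    zone_a: Zone
    zone_b: Zone
    difference_log_odds: float
    z_statistic: float
    p_value: float
    method: str = "wald"  # "wald" or "fisher_exact" (separation fallback)


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected rank AUC (Mann-Whitney), oriented into [0.5, 1].

    Ties receive half credit. Equivalent to the O(n^2) scan over all
    (positive, negative) pairs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = labels.sum()
    n0 = (~labels).sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = stats.rankdata(scores)  # average ranks handle ties
    auc = (ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    return float(max(auc, 1 - auc))


def _counts_from_plots(plots: Sequence[SamplePlot]) -> dict[Zone, tuple[int, int]]:
    counts: dict[Zone, list[int]] = {}
    for p in plots:
        if p.presence is None:
            raise ValueError("all plots must be scored before model fitting")
        c = counts.setdefault(p.zone, [0, 0])
        c[0] += p.presence
        c[1] += 1
    return {z: (c[0], c[1]) for z, c in counts.items()}


def fit_zone_model(plots: Sequence[SamplePlot], reference: Zone = Zone.BURROW) -> ZoneModelFit:
    """Fit the binomial zone model to scored plots from one year."""
    return fit_zone_counts(_counts_from_plots(plots), reference=reference)


def fit_zone_counts(
    counts: Mapping[Zone, tuple[int, int]], reference: Zone = Zone.BURROW
) -> ZoneModelFit:
    """Fit the binomial zone model from aggregated per-zone counts.

    ``counts`` maps each zone to ``(n_present, n_plots)``. The GLM is fit
    by IRLS on the aggregated binomial likelihood — identical to the
    per-plot fit, but O(#zones) instead of O(#plots).
    """
    counts = {Zone(z): (int(s), int(n)) for z, (s, n) in counts.items()}
    if len(counts) < 2:
        raise ValueError("need at least 2 zones")
    for z, (s, n) in counts.items():
        if n <= 0 or s < 0 or s > n:
            raise ValueError(f"invalid counts for zone {z}: {s}/{n}")
    total_s = sum(s for s, _ in counts.values())
    total_n = sum(n for _, n in counts.values())
    if total_s == 0 or total_s == total_n:
        raise ValueError("need at least one presence and one absence overall")
    if reference not in counts:
        raise ValueError(f"reference zone {reference} has no observations")

    zones = [reference] + sorted((z for z in counts if z != reference), key=lambda z: z.value)
    succ = np.array([counts[z][0] for z in zones], dtype=float)
    tot = np.array([counts[z][1] for z in zones], dtype=float)
    endog = np.column_stack([succ, tot - succ])
    k = len(zones)
    exog = np.zeros((k, k))
    exog[:, 0] = 1.0
    for j in range(1, k):
        exog[j, j] = 1.0

    separated = [z for z in zones if counts[z][0] in (0, counts[z][1])]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation makes IRLS noisy; flagged below
        res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(tol=1e-10, maxiter=200)

    probs = {z: float(p) for z, p in zip(zones, res.predict(exog))}
    # per-plot fitted scores for the rank AUC
    scores, labels = [], []
    for z in zones:
        s, n = counts[z]
        scores += [probs[z]] * n
        labels += [1] * s + [0] * (n - s)
    auc = rank_auc(np.array(scores), np.array(labels))

    return ZoneModelFit(
        zones=zones,
        reference=reference,
        counts=counts,
        coefficients=np.asarray(res.params),
        standard_errors=np.asarray(res.bse),
        covariance=np.asarray(res.cov_params()),
        fitted_probability=probs,
        auc=auc,
        n_observations=int(total_n),
        separated_zones=separated,
    )


def pairwise_lsd(fit: ZoneModelFit) -> list[PairwiseContrast]:
    """All pairwise zone contrasts, LSD-style (no multiplicity adjustment).

    Each contrast is a two-sided Wald z test on the difference of zone
    log-odds with covariance taken from the fit. Pairs involving a
    separated zone use Fisher's exact test on the 2x2 table instead
    (``method="fisher_exact"``, z reported as NaN).
    """
    out = []
    zone_index = {z: i for i, z in enumerate(fit.zones)}
    for za, zb in itertools.combinations(fit.zones, 2):
        sa, na = fit.counts[za]
        sb, nb = fit.counts[zb]
        if za in fit.separated_zones or zb in fit.separated_zones:
            table = [[sa, na - sa], [sb, nb - sb]]
            p = float(stats.fisher_exact(table)[1])
            diff = float("nan")
            out.append(PairwiseContrast(za, zb, diff, float("nan"), p, method="fisher_exact"))
            continue
        c = np.zeros(len(fit.zones))
        if za != fit.reference:
            c[zone_index[za]] = 1.0
        if zb != fit.reference:
            c[zone_index[zb]] = -1.0
        diff = float(c @ fit.coefficients)
        se = float(np.sqrt(c @ fit.covariance @ c))
        z = diff / se
        p = float(2 * stats.norm.sf(abs(z)))
        out.append(PairwiseContrast(za, zb, diff, z, min(p, 1.0), method="wald"))
    return out
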