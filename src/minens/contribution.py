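"""Per-predictor contribution scores.

A contribution score quantifies how much unique value a component predictor
brings to an ensemble. For each protein the predictors cast categorical
votes; a predictor is rewarded for being *correct while in the minority*
(it knows something the crowd does not) and penalised for being wrong,
most heavily when it is wrong together with the majority.

With per-protein vote counts

* ``v_max``     — size of the largest vote group,
* ``v_sec``     — size of the second-largest vote group (0 if only one
  distinct label was voted),
* ``v_correct`` — number of votes equal to the true label,
* ``v_p(i)``    — number of predictors (including i itself) voting the same
  label as predictor i,

the per-protein term for predictor i is

    alpha_i * (2*v_max - v_p(i)) + beta_i * v_sec
        + theta_i * (v_correct - v_p(i) - v_max)

where exactly one of the indicators fires: ``alpha_i`` (correct, label
group strictly smaller than the majority group), ``beta_i`` (correct,
label group is a majority group) or ``theta_i`` (incorrect). A predictor's
final score is the sum over all proteins; scores are reported raw and
z-normalised across predictors, (CS - mu) / sigma with population sigma.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .io import NA_LABEL, PredictionTable


@dataclass(frozen=True)
class VoteProfile:
    """Vote counts and indicator flags for a single protein."""

    labels: tuple[str, ...]
    true_label: str
    v_max: int
    v_sec: int
    v_correct: int
    v_agree: tuple[int, ...]  # v_p(i), including predictor i itself
    alpha: tuple[int, ...]
    beta: tuple[int, ...]
    theta: tuple[int, ...]

    @property
    def n_predictors(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class ContributionResult:
    """Raw and z-normalised contribution scores for a predictor panel."""

    predictor_names: list[str]
    raw_scores: np.ndarray
    normalized_scores: np.ndarray
    mu: float
    sigma: float
    n_proteins_used: int


def vote_profile(row, true_label: str) -> VoteProfile:
    """Vote counts and contribution indicators for one protein's row.

    Parameters
    ----------
    row : sequence of str
        Per-predictor predicted labels (at least two, none the ``NA``
        sentinel).
    true_label : str
        The protein's curated localization.
    """
    labels = tuple(row)
    if len(labels) < 2:
        raise ValueError("need at least 2 predictors to form a vote profile")
    if any(lab == NA_LABEL for lab in labels):
        raise ValueError("vote profile undefined for rows with missing predictions")
    counts = Counter(labels)
    sizes = sorted(counts.values(), reverse=True)
    v_max = sizes[0]
    v_sec = sizes[1] if len(sizes) > 1 else 0
    v_correct = counts.get(true_label, 0)
    v_agree = tuple(counts[lab] for lab in labels)
    alpha, beta, theta = [], [], []
    for lab, agree in zip(labels, v_agree):
        correct = lab == true_label
        a = int(correct and agree < v_max)
        b = int(correct and agree == v_max)
        alpha.append(a)
        beta.append(b)
        theta.append(int(not correct))
    return VoteProfile(
        labels=labels,
        true_label=true_label,
        v_max=v_max,
        v_sec=v_sec,
        v_correct=v_correct,
        v_agree=v_agree,
        alpha=tuple(alpha),
        beta=tuple(beta),
        theta=tuple(theta),
    )


def protein_contribution(profile: VoteProfile, i: int) -> float:
    """Per-protein contribution of predictor ``i`` (0-based index)."""
    if not 0 <= i < profile.n_predictors:
        raise IndexError(f"predictor index {i} out of range")
    a, b, t = profile.alpha[i], profile.beta[i], profile.theta[i]
    vp = profile.v_agree[i]
    return float(
        a * (2 * profile.v_max - vp)
        + b * profile.v_sec
        + t * (profile.v_correct - vp - profile.v_max)
    )


def contribution_scores(table: PredictionTable) -> ContributionResult:
    """Contribution scores of every predictor in a truth-labelled table.

    Rows containing the ``NA`` sentinel are excluded. The raw score of a
    predictor is the sum of its per-protein contributions; normalised
    scores are (CS - mu) / sigma with mu, sigma the mean and population
    standard deviation across predictors (all zeros when sigma is 0).
    """
    if table.true_labels is None:
        raise ValueError("contribution scores require true labels")
    if table.n_proteins < 1:
        raise ValueError("empty table")
    mask = table.complete_rows()
    X = table.predictions[mask]
    truth = np.asarray(table.true_labels, dtype=object)[mask]
    n, p = X.shape
    if n == 0:
        raise ValueError("no complete rows (every row has a missing prediction)")

    raw = np.zeros(p)
    for j in range(n):
        row = X[j]
        counts = Counter(row)
        sizes = sorted(counts.values(), reverse=True)
        v_max = sizes[0]
        v_sec = sizes[1] if len(sizes) > 1 else 0
        v_correct = counts.get(truth[j], 0)
        for i in range(p):
            vp = counts[row[i]]
            if row[i] == truth[j]:
                raw[i] += 2 * v_max - vp if vp < v_max else v_sec
            else:
                raw[i] += v_correct - vp - v_max

    mu = float(raw.mean())
    sigma = float(raw.std())  # population sd across predictors
    normalized = (raw - mu) / sigma if sigma > 0 else np.zeros_like(raw)
    return ContributionResult(
        predictor_names=list(table.predictor_names),
        raw_scores=raw,
        normalized_scores=normalized,
        mu=mu,
        sigma=sigma,
        n_proteins_used=int(n),
    )
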