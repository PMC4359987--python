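"""Signal-detection analysis of the two-interval loudness judgment.

The loudness comparison is scored as a yes/no detection problem: the signal
class is "second tone physically softer than the first", and the response
"first_louder" (equivalently, second tone softer) counts as a hit.  With this
convention the standard criterion ``c = -(z(H) + z(FA)) / 2`` is positive
when the observer is biased toward reporting the *first* tone as the softer —
the direction in which sensory attenuation of the first tone pushes the
judgment.

Also provided: the resampling test used to flag participants with residual
prime awareness, and one-tailed paired t-tests for the behavioral contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SDTResult",
    "AwarenessTest",
    "sdt_from_counts",
    "condition_sdt",
    "awareness_resampling_test",
    "paired_t_one_tailed",
    "behavioral_summary",
]


@dataclass
class SDTResult:
    d_prime: float
    criterion: float  # positive = bias to report the first tone as the softer
    hit_rate: float
    fa_rate: float
    n_signal: int
    n_noise: int


@dataclass
class AwarenessTest:
    observed_dprime: float
    null_dprimes: np.ndarray
    p_value: float
    excluded: bool


def _corrected_rates(n_hit, n_miss, n_fa, n_cr):
    """Hit/FA rates; the 0.5 log-linear adjustment is applied only when a
    rate would otherwise be 0 or 1, keeping interior estimates untouched."""
    n_signal = n_hit + n_miss
    n_noise = n_fa + n_cr
    if n_signal < 1 or n_noise < 1:
        raise ValueError("need at least one signal and one noise trial")

    def rate(k, n):
        if k == 0 or k == n:
            return (k + 0.5) / (n + 1.0)
        return k / n

    return rate(n_hit, n_signal), rate(n_fa, n_noise), n_signal, n_noise


def sdt_from_counts(n_hit: int, n_miss: int, n_fa: int, n_cr: int) -> SDTResult:
    """d' and criterion from a 2x2 response table.

    d' = z(H) - z(FA); c = -(z(H) + z(FA)) / 2 under the sign convention
    stated in the module docstring.
    """
    h, fa, n_signal, n_noise = _corrected_rates(n_hit, n_miss, n_fa, n_cr)
    zh, zfa = stats.norm.ppf(h), stats.norm.ppf(fa)
    return SDTResult(
        d_prime=zh - zfa,
        criterion=-(zh + zfa) / 2.0,
        hit_rate=h,
        fa_rate=fa,
        n_signal=n_signal,
        n_noise=n_noise,
    )


def _dprime_vec(n_hit, n_signal, n_fa, n_noise):
    """Vectorized d' from count arrays, same boundary correction as
    :func:`sdt_from_counts`."""
    n_hit = np.asarray(n_hit, dtype=float)
    n_fa = np.asarray(n_fa, dtype=float)
    extreme_h = (n_hit == 0) | (n_hit == n_signal)
    extreme_f = (n_fa == 0) | (n_fa == n_noise)
    h = np.where(extreme_h, (n_hit + 0.5) / (n_signal + 1.0), n_hit / n_signal)
    fa = np.where(extreme_f, (n_fa + 0.5) / (n_noise + 1.0), n_fa / n_noise)
    return stats.norm.ppf(h) - stats.norm.ppf(fa)


def _sdt_from_labels(stimulus_labels, responses, signal_label, hit_response):
    stimulus_labels = np.asarray(stimulus_labels)
    responses = np.asarray(responses)
    sig = stimulus_labels == signal_label
    hit_resp = responses == hit_response
    n_hit = int(np.sum(sig & hit_resp))
    n_miss = int(np.sum(sig & ~hit_resp))
    n_fa = int(np.sum(~sig & hit_resp))
    n_cr = int(np.sum(~sig & ~hit_resp))
    return sdt_from_counts(n_hit, n_miss, n_fa, n_cr)


def condition_sdt(trials: pd.DataFrame) -> pd.DataFrame:
    """Per (subject, condition) SDT analysis of the loudness judgments.

    Error trials (no loudness response) must already be absent, mirroring the
    exclusion of trials with an incorrect or missing target response.
    Returns a tidy frame with one row per cell.
    """
    rows = []
    for (subject, condition), cell in trials.groupby(
        ["subject_id", "condition"], sort=True
    ):
        classes = set(cell["tone2_class"])
        if classes != {"softer", "louder"}:
            raise ValueError(
                f"cell (subject {subject}, {condition}) lacks both stimulus "
                f"classes: found {sorted(classes)}"
            )
        res = _sdt_from_labels(
            cell["tone2_class"], cell["loudness_response"], "softer", "first_louder"
        )
        rows.append(
            {
                "subject_id": subject,
                "condition": condition,
                "d_prime": res.d_prime,
                "criterion": res.criterion,
                "hit_rate": res.hit_rate,
                "fa_rate": res.fa_rate,
                "n_trials": len(cell),
            }
        )
    return pd.DataFrame(rows)


def awareness_resampling_test(
    responses,
    stimulus_labels,
    n_resamples: int = 100_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> AwarenessTest:
    """Nonparametric test of above-chance prime recognition.

    The null distribution is built by redrawing, for every trial, a response
    at random (with replacement) from all of the subject's responses while
    the stimulus labels stay fixed, and recomputing d' each time.  The
    p-value is the proportion of null d' values >= the observed d' (ties
    count as exceedance); the subject is flagged for exclusion when
    p < ``alpha``.

    Because responses are redrawn independently of the trial, the null hit
    and false-alarm counts are binomial with the subject's marginal response
    probability, which is how the resampling is carried out here.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    responses = np.asarray(responses)
    stimulus_labels = np.asarray(stimulus_labels)
    if responses.shape != stimulus_labels.shape:
        raise ValueError("responses and stimulus_labels must have equal length")
    labels = np.unique(stimulus_labels)
    if len(labels) != 2:
        raise ValueError("need exactly two stimulus labels")
    signal_label, noise_label = labels[0], labels[1]
    # the "hit" response is the one matching the signal label when labels and
    # responses share a vocabulary; otherwise take the first response value
    response_values = np.unique(responses)
    hit_response = signal_label if signal_label in response_values else response_values[0]

    observed = _sdt_from_labels(
        stimulus_labels, responses, signal_label, hit_response
    ).d_prime

    rng = np.random.default_rng(seed)
    n_signal = int(np.sum(stimulus_labels == signal_label))
    n_noise = len(stimulus_labels) - n_signal
    p_hit_resp = float(np.mean(responses == hit_response))
    null_hits = rng.binomial(n_signal, p_hit_resp, size=n_resamples)
    null_fas = rng.binomial(n_noise, p_hit_resp, size=n_resamples)
    null = _dprime_vec(null_hits, n_signal, null_fas, n_noise)
    p = float(np.mean(null >= observed))
    return AwarenessTest(
        observed_dprime=observed,
        null_dprimes=null,
        p_value=p,
        excluded=bool(p < alpha),
    )


def paired_t_one_tailed(values_a, values_b, direction: str = "greater"):
    """One-tailed dependent-samples t-test on a - b.

    ``direction`` states the alternative for the mean difference ("greater"
    or "less").  Zero-variance differences yield t = +/-inf with p = 0 or 1
    (t = 0, p = 0.5 when all differences are zero) and a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    diff = a - b
    n = len(diff)
    df = n - 1
    sd = diff.std(ddof=1)
    if sd == 0.0:
        m = diff.mean()
        if m == 0.0:
            return 0.0, df, 0.5
        warnings.warn("zero-variance paired differences; returning infinite t")
        t = np.inf if m > 0 else -np.inf
        if direction == "greater":
            p = 0.0 if m > 0 else 1.0
        else:
            p = 0.0 if m < 0 else 1.0
        return t, df, p
    t, p = stats.ttest_rel(a, b, alternative=direction)
    return float(t), df, float(p)


def behavioral_summary(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject behavioral table and the group-level one-tailed contrasts.

    The contrasts test the directional predictions: compatible trials are
    slower, more error prone and carry a larger (more positive) criterion;
    d' is tested two-ways informally via the same one-tailed machinery but
    reported with the compatible > incompatible alternative.
    """
    per = []
    for subject, sub in trials.groupby("subject_id", sort=True):
        row = {"subject_id": subject}
        for condition in ("compatible", "incompatible"):
            cond = sub[sub["condition"] == condition]
            correct = cond[cond["target_response_correct"]]
            row[f"rt_{condition}"] = correct["rt"].mean()
            row[f"error_rate_{condition}"] = 1.0 - cond["target_response_correct"].mean()
        per.append(row)
    per = pd.DataFrame(per).set_index("subject_id")

    correct = trials[trials["target_response_correct"]]
    sdt = condition_sdt(correct)
    wide = sdt.pivot(index="subject_id", columns="condition", values=["d_prime", "criterion"])
    per["d_prime_compatible"] = wide[("d_prime", "compatible")]
    per["d_prime_incompatible"] = wide[("d_prime", "incompatible")]
    per["criterion_compatible"] = wide[("criterion", "compatible")]
    per["criterion_incompatible"] = wide[("criterion", "incompatible")]

    contrasts = []
    for measure, direction in [
        ("rt", "greater"),
        ("error_rate", "greater"),
        ("criterion", "greater"),
        ("d_prime", "greater"),
    ]:
        t, df, p = paired_t_one_tailed(
            per[f"{measure}_compatible"], per[f"{measure}_incompatible"], direction
        )
        contrasts.append(
            {
                "contrast": f"{measure}: compatible > incompatible",
                "t": t,
                "df": df,
                "p_one_tailed": p,
                "mean_compatible": per[f"{measure}_compatible"].mean(),
                "mean_incompatible": per[f"{measure}_incompatible"].mean(),
            }
        )
    return per, pd.DataFrame(contrasts)
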