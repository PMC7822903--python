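"""Synthetic four-group study cohort with calibrated effect sizes.

The generator emulates the study population: 434 children in four
diagnostic groups (197 typically developing controls, 34 ASD, 104 ADHD,
99 ASD+ADHD) with group-specific age distributions. Each participant is
a generative observer whose latent thresholds are drawn from a
truncated-normal control baseline, shifted per group to realize target
Cohen's d values and tilted by a small age effect. Caregiver
questionnaire scores are injected conditional on the *measured*
(staircase-estimated) thresholds so that target Pearson correlations are
recovered directly at analysis time.

Effect-size targets are defined on the measured-threshold scale.
Because staircase measurement noise attenuates latent group separations,
:func:`calibrate_generator` inflates the latent shifts until the
measured-scale d matches its target.
"""
from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .instruments import GROUPS, INSTRUMENTS, Instrument, mask_for
from .metrics import estimate_threshold
from .observer import ChannelParams, Observer
from .protocols import (AMPLITUDE, DETECTION, FREQUENCY, PROTOCOLS, TOJ,
                        PracticeGateError, ProtocolSpec, TrialLog,
                        default_protocols, run_protocol)


def derive_seed(master_seed: int, *parts) -> int:
    """Stable sub-seed from a master seed and a label path (CRC-32 based)."""
    key = ":".join([str(master_seed), *map(str, parts)])
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class CorrelationTarget:
    """Target Pearson r between one measured metric and one subscale."""

    metric: str          # e.g. "detection_threshold"
    instrument: str      # key into INSTRUMENTS
    subscale: str
    r: float
    mask: str = "all"    # population on which the correlation is injected

    def __post_init__(self) -> None:
        if not -1.0 < self.r < 1.0:
            raise ValueError("|r| must be < 1")


#: Correlation structure of the study's significant (and deliberately
#: null) questionnaire associations, on the populations analysed.
DEFAULT_CORRELATION_TARGETS: tuple[CorrelationTarget, ...] = (
    CorrelationTarget("detection_threshold", "seq", "total_hyper", 0.28, "all"),
    CorrelationTarget("detection_threshold", "seq", "total_hypo", 0.37, "all"),
    CorrelationTarget("detection_threshold", "seq", "total_seeking", 0.31, "all"),
    CorrelationTarget("detection_threshold", "spm", "social_participation", 0.22, "all"),
    CorrelationTarget("detection_threshold", "spm", "body_awareness", 0.29, "all"),
    CorrelationTarget("amplitude_discrimination_threshold", "ados",
                      "communication_social", 0.25, "asd"),
    CorrelationTarget("frequency_discrimination_threshold", "ados",
                      "communication_social", 0.22, "asd"),
    CorrelationTarget("detection_threshold", "conners", "hyperactivity", 0.57,
                      "adhd_only"),
    CorrelationTarget("detection_threshold", "dupaul", "hyperactivity", 0.32,
                      "adhd_only"),
    CorrelationTarget("temporal_order_judgement_threshold", "dupaul",
                      "inattention", 0.30, "adhd_only"),
    CorrelationTarget("temporal_order_judgement_threshold", "conners",
                      "inattention", 0.06, "adhd_only"),
)


def _default_group_sizes() -> dict[str, int]:
    return {"TDC": 197, "ASD": 34, "ADHD": 104, "ASD+ADHD": 99}


def _default_ages() -> dict[str, tuple[float, float]]:
    return {"TDC": (10.20, 1.20), "ASD": (10.34, 1.25),
            "ADHD": (9.94, 1.20), "ASD+ADHD": (10.48, 1.35)}


def _default_effect_sizes() -> dict[str, dict[str, float]]:
    return {
        DETECTION: {"ASD": 0.34, "ADHD": 0.60, "ASD+ADHD": 0.70},
        AMPLITUDE: {"ASD": 0.34, "ADHD": 0.60, "ASD+ADHD": 0.70},
        FREQUENCY: {"ASD": 0.34, "ADHD": 0.59, "ASD+ADHD": 0.70},
        TOJ: {"ASD": 0.25, "ADHD": 0.24, "ASD+ADHD": 0.48},
    }


def _default_baseline() -> dict[str, tuple[float, float]]:
    # control-group latent threshold mean/SD in tracked units; order-of-
    # magnitude plausible for children, configurable (absolute levels are
    # configuration — only standardized quantities are calibrated)
    return {DETECTION: (8.0, 4.0), AMPLITUDE: (40.0, 25.0),
            FREQUENCY: (4.0, 2.5), TOJ: (80.0, 50.0)}


def _default_sigma() -> dict[str, float]:
    return {DETECTION: 3.0, AMPLITUDE: 15.0, FREQUENCY: 1.5, TOJ: 30.0}


def _default_age_slope() -> dict[str, float]:
    # tracked units per year of age (thresholds improve as children mature)
    return {DETECTION: -0.5, AMPLITUDE: -3.0, FREQUENCY: -0.25, TOJ: -6.0}


@dataclass(frozen=True)
class CohortSpec:
    group_sizes: dict[str, int] = field(default_factory=_default_group_sizes)
    age_mean_sd: dict[str, tuple[float, float]] = field(default_factory=_default_ages)
    effect_sizes: dict[str, dict[str, float]] = field(default_factory=_default_effect_sizes)
    baseline_theta: dict[str, tuple[float, float]] = field(default_factory=_default_baseline)
    sigma: dict[str, float] = field(default_factory=_default_sigma)
    age_slope: dict[str, float] = field(default_factory=_default_age_slope)
    lapse_range: tuple[float, float] = (0.0, 0.05)
    rt_median_ms: float = 800.0
    rt_median_log_sd: float = 0.2
    rt_spread: float = 0.35
    toj_completion_fraction: float = 0.64
    inflation: dict[tuple[str, str], float] = field(default_factory=dict)
    correlation_targets: tuple[CorrelationTarget, ...] = DEFAULT_CORRELATION_TARGETS
    seq_shared_loading: float = 0.85
    score_mean: float = 50.0
    score_sd: float = 10.0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        if not (0.0 < self.toj_completion_fraction <= 1.0):
            raise ValueError("toj_completion_fraction must lie in (0, 1]")

    def groups(self) -> list[str]:
        return [g for g in GROUPS if g in self.group_sizes]


def null_spec(**overrides) -> CohortSpec:
    """Default spec with every group effect set to zero (null generator)."""
    zero = {p: {g: 0.0 for g in ("ASD", "ADHD", "ASD+ADHD")}
            for p in PROTOCOLS}
    return replace(CohortSpec(), effect_sizes=zero, **overrides)


@dataclass
class Participant:
    id: str
    group: str
    age_years: float
    observer: Observer
    completed: set[str]
    questionnaires: dict[str, float] = field(default_factory=dict)


def _truncated_normal(rng, loc: float, scale: float, low: float = 0.0) -> float:
    """One draw from N(loc, scale) truncated below at ``low`` (inverse CDF)."""
    a = ndtr((low - loc) / scale)
    u = a + rng.random() * (1.0 - a)
    # guard against u == 1 rounding
    u = min(u, 1.0 - 1e-12)
    return loc + scale * float(ndtri(u))


def generate_cohort(spec: CohortSpec, seed: int) -> list[Participant]:
    """Draw a full cohort: ages, latent observers, completion flags.

    Deterministic given ``spec`` and ``seed``. Latent thresholds are
    truncated at zero; the group shift for protocol ``p`` and group ``g``
    is ``d[p][g] * baseline_sd[p] * inflation[(p, g)]``.
    """
    rng = np.random.default_rng(seed)
    participants: list[Participant] = []
    counter = 0
    log_rt = math.log(spec.rt_median_ms)
    for group in spec.groups():
        mean_age, sd_age = spec.age_mean_sd[group]
        for _ in range(spec.group_sizes[group]):
            counter += 1
            pid = f"P{counter:04d}"
            age = rng.normal(mean_age, sd_age)
            lapse = rng.uniform(*spec.lapse_range)
            rt_med = math.exp(rng.normal(log_rt, spec.rt_median_log_sd))
            channels = {}
            for protocol in PROTOCOLS:
                base_m, base_sd = spec.baseline_theta[protocol]
                d = spec.effect_sizes.get(protocol, {}).get(group, 0.0)
                f = spec.inflation.get((protocol, group), 1.0)
                loc = (base_m + d * f * base_sd
                       + spec.age_slope[protocol] * (age - 10.0))
                theta = _truncated_normal(rng, loc, base_sd)
                channels[protocol] = ChannelParams(
                    theta=theta, sigma=spec.sigma[protocol], lapse=lapse,
                    rt_median_ms=rt_med, rt_spread=spec.rt_spread)
            completed = set(PROTOCOLS)
            if rng.random() >= spec.toj_completion_fraction:
                completed.discard(TOJ)
            participants.append(Participant(pid, group, age,
                                            Observer(channels), completed))
    return participants


def participants_frame(participants: Sequence[Participant]) -> pd.DataFrame:
    return pd.DataFrame({
        "participant_id": [p.id for p in participants],
        "group": [p.group for p in participants],
        "age_years": [p.age_years for p in participants],
        "completed": [";".join(sorted(p.completed)) for p in participants],
        "toj_completed": [TOJ in p.completed for p in participants],
    })


def observers_frame(participants: Sequence[Participant]) -> pd.DataFrame:
    """Observer parameter table, one row per participant × protocol."""
    rows = []
    for p in participants:
        for protocol, ch in p.observer.channels.items():
            rows.append((p.id, protocol, ch.theta, ch.sigma, ch.lapse,
                         ch.guess, ch.rt_median_ms, ch.rt_spread))
    return pd.DataFrame(rows, columns=[
        "participant_id", "protocol_id", "theta", "sigma", "lapse", "guess",
        "rt_median_ms", "rt_spread"])


def simulate_runs(participants: Sequence[Participant], base_seed: int,
                  specs: dict[str, ProtocolSpec] | None = None,
                  protocols: Iterable[str] | None = None
                  ) -> list[TrialLog]:
    """Run the staircase battery for every participant × completed protocol.

    Per-run seeds derive from ``base_seed`` and the participant/protocol
    labels, so cohorts reproduce under any iteration order. Participants
    who fail a protocol's practice gate simply contribute no run for it.
    """
    specs = specs or default_protocols()
    wanted = list(protocols) if protocols is not None else list(PROTOCOLS)
    logs: list[TrialLog] = []
    for p in participants:
        for protocol in wanted:
            if protocol not in p.completed:
                continue
            run_seed = derive_seed(base_seed, p.id, protocol)
            try:
                logs.append(run_protocol(specs[protocol], p.observer,
                                         run_seed, p.id))
            except PracticeGateError:
                continue
    return logs


def simulate_outcomes(participants: Sequence[Participant], base_seed: int,
                      specs: dict[str, ProtocolSpec] | None = None,
                      protocols: Iterable[str] | None = None) -> pd.DataFrame:
    """Measured outcome table (threshold/accuracy/RT/reversals per run)."""
    specs = specs or default_protocols()
    wanted = list(protocols) if protocols is not None else list(PROTOCOLS)
    rows = []
    for p in participants:
        for protocol in wanted:
            if protocol not in p.completed:
                continue
            run_seed = derive_seed(base_seed, p.id, protocol)
            try:
                log = run_protocol(specs[protocol], p.observer, run_seed, p.id)
            except PracticeGateError:
                continue
            est = estimate_threshold(log, specs[protocol])
            rows.append((p.id, protocol, est.threshold, est.accuracy,
                         est.median_rt_ms, est.n_reversals, est.n_trials_used))
    return pd.DataFrame(rows, columns=[
        "participant_id", "protocol_id", "threshold", "accuracy",
        "median_rt_ms", "n_reversals", "n_trials_used"])


# ---------------------------------------------------------------------------
# effect-size calibration on the measured scale

def _measured_d_one_replicate(spec: CohortSpec, protocol: str, group: str,
                              seed: int) -> float:
    from .stats import age_adjusted_cohens_d

    reduced = replace(spec, group_sizes={
        "TDC": spec.group_sizes["TDC"], group: spec.group_sizes[group]})
    participants = generate_cohort(reduced, seed)
    outcomes = simulate_outcomes(participants, derive_seed(seed, "runs"),
                                 protocols=[protocol])
    merged = outcomes.merge(participants_frame(participants),
                            on="participant_id")
    try:
        return age_adjusted_cohens_d(merged, "threshold", group)
    except ValueError:
        # practice-gate attrition can empty a tiny group; no contrast then
        return float("nan")


def measured_effect_size(spec: CohortSpec, protocol: str, group: str,
                         n_replicates: int, seed: int) -> float:
    """Mean age-adjusted Cohen's d (group vs TDC) on the measured scale."""
    ds = [_measured_d_one_replicate(spec, protocol, group,
                                    derive_seed(seed, protocol, group, k))
          for k in range(n_replicates)]
    valid = np.asarray(ds)[np.isfinite(ds)]
    if valid.size < max(1, n_replicates // 2):
        raise RuntimeError(
            f"too few evaluable replicates for {(protocol, group)}")
    return float(valid.mean())


def calibrate_generator(spec: CohortSpec,
                        targets: Iterable[tuple[str, str]] | None = None,
                        n_replicates: int = 75, n_iter: int = 3,
                        seed: int = 0) -> CohortSpec:
    """Inflate latent group separations until measured d matches its target.

    ``targets`` is a list of ``(protocol, group)`` pairs (default: every
    pair with a nonzero configured effect size). The measured-scale d
    responds essentially proportionally to the latent inflation factor
    ``f``, so calibration estimates the slope ``s`` of ``d(f) = s·f`` by
    pooling every (f, d) measurement taken so far — ``n_replicates``
    replicate cohorts per iteration — and sets ``f = target / s``.
    Pooling makes the factor robust to a single noisy replicate batch.
    Raises if the response slope stays indistinguishable from zero.
    """
    if targets is None:
        targets = [(p, g) for p, gs in spec.effect_sizes.items()
                   for g, d in gs.items() if d != 0.0]
    inflation = dict(spec.inflation)
    for protocol, group in targets:
        d_target = spec.effect_sizes[protocol][group]
        if d_target == 0.0:
            inflation[(protocol, group)] = 1.0
            continue
        f = inflation.get((protocol, group), 1.0)
        points: list[tuple[float, float]] = []
        slope = 0.0
        for it in range(n_iter):
            trial = replace(spec, inflation={**inflation,
                                             (protocol, group): f})
            d_meas = measured_effect_size(
                trial, protocol, group, n_replicates,
                derive_seed(seed, "cal", protocol, group, it))
            points.append((f, d_meas))
            slope = (sum(fi * di for fi, di in points)
                     / sum(fi * fi for fi, _ in points))
            if slope <= 0.02:
                # noisy or flat response: push the shift up to elicit a
                # measurable one before giving up
                f = min(f * 2.0, 8.0)
            else:
                f = float(np.clip(d_target / slope, 0.1, 8.0))
        if slope <= 0.02:
            raise RuntimeError(
                f"calibration failed for {(protocol, group)}: "
                f"no measurable response to the latent shift")
        inflation[(protocol, group)] = f
    return replace(spec, inflation=inflation)


# ---------------------------------------------------------------------------
# questionnaire injection

class InjectionError(ValueError):
    """Correlation targets infeasible or mask empty."""


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.nanstd(x)
    if sd == 0 or not np.isfinite(sd):
        raise InjectionError("zero-variance metric in injection mask")
    return (x - np.nanmean(x)) / sd


def inject_questionnaires(participants: Sequence[Participant],
                          outcomes: pd.DataFrame, spec: CohortSpec,
                          rng) -> pd.DataFrame:
    """Generate questionnaire scores correlated with measured thresholds.

    Each subscale score is a linear combination of the standardized
    measured metrics named by the spec's correlation targets plus
    Gaussian noise, built so the population correlation inside the
    target's mask equals the target r. The three SEQ composite scores
    (hyper-, hypo-responsivity, seeking) additionally share a latent
    responsivity factor so their pairwise correlations exceed 0.75.
    Scores are emitted on a T-score-like scale (mean 50, SD 10) and only
    for instruments a participant's group receives; participants inside
    a mask who lack a metric (e.g. order-judgement non-completers)
    receive noise-only scores for the affected subscale.

    Returns a wide table (participant_id + one column per subscale) and
    fills ``participant.questionnaires`` in place.
    """
    pframe = participants_frame(participants)
    n = len(pframe)
    if n == 0:
        raise InjectionError("empty cohort")
    groups = pframe["group"]
    wide = outcomes.pivot(index="participant_id", columns="protocol_id",
                          values="threshold")
    wide.columns = [f"{c}_threshold" for c in wide.columns]
    wide = wide.reindex(pframe["participant_id"])
    metrics = {c: wide[c].to_numpy(float) for c in wide.columns}

    # group targets by instrument/subscale
    by_scale: dict[tuple[str, str], list[CorrelationTarget]] = {}
    for t in spec.correlation_targets:
        by_scale.setdefault((t.instrument, t.subscale), []).append(t)

    out = pd.DataFrame({"participant_id": pframe["participant_id"]})
    seq_latent = rng.standard_normal(n)  # shared responsivity factor

    for inst_name, inst in INSTRUMENTS.items():
        available = groups.isin(inst.available_groups).to_numpy()
        seq_totals: dict[str, np.ndarray] = {}
        for subscale in inst.subscales:
            targets = by_scale.get((inst_name, subscale), [])
            z = np.full(n, np.nan)
            noise = rng.standard_normal(n)
            if inst_name == "seq" and subscale.startswith(("social_",
                                                           "nonsocial_")):
                # facet scores load on their composite
                comp = "total_" + subscale.split("_", 1)[1]
                base = seq_totals[comp]
                load = 0.9
                z = load * base + math.sqrt(1 - load ** 2) * noise
            elif not targets:
                z = noise
            else:
                masks = {t.mask for t in targets}
                if len(masks) > 1:
                    raise InjectionError(
                        f"conflicting masks for {inst_name}/{subscale}")
                mask = (mask_for(masks.pop(), groups).to_numpy() & available)
                if not mask.any():
                    raise InjectionError(
                        f"empty mask for {inst_name}/{subscale}")
                usable = [t for t in targets if t.metric in metrics]
                pred = np.column_stack(
                    [metrics[t.metric] for t in usable]) if usable else \
                    np.empty((n, 0))
                complete = mask & np.isfinite(pred).all(axis=1)
                z = noise.copy()
                if usable and complete.sum() >= 3:
                    zpred = np.column_stack(
                        [_zscore(pred[complete, j])
                         for j in range(pred.shape[1])])
                    r = np.array([t.r for t in usable])
                    cov = np.corrcoef(zpred, rowvar=False) \
                        if zpred.shape[1] > 1 else np.ones((1, 1))
                    b = np.linalg.solve(cov, r)
                    shared = (spec.seq_shared_loading
                              if inst_name == "seq" else 0.0)
                    resid_var = 1.0 - float(b @ cov @ b) - shared ** 2
                    if resid_var <= 0.01:
                        raise InjectionError(
                            f"targets jointly infeasible for "
                            f"{inst_name}/{subscale}")
                    signal = zpred @ b
                    if shared:
                        signal = signal + shared * seq_latent[complete]
                    z[complete] = signal + math.sqrt(resid_var) * \
                        noise[complete]
            if inst_name == "seq" and subscale.startswith("total_"):
                seq_totals[subscale] = z.copy()
            score = spec.score_mean + spec.score_sd * z
            score[~available] = np.nan
            out[f"{inst_name}_{subscale}"] = score

    for i, p in enumerate(participants):
        p.questionnaires = {
            c: float(out[c].iloc[i]) for c in out.columns[1:]
            if np.isfinite(out[c].iloc[i])}
    return out


def replicate_cohort(spec: CohortSpec, seed: int,
                     protocols: Iterable[str] | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """One full synthetic replicate: participants, outcomes, questionnaires."""
    participants = generate_cohort(spec, seed)
    outcomes = simulate_outcomes(participants, derive_seed(seed, "runs"),
                                 protocols=protocols)
    rng = np.random.default_rng(derive_seed(seed, "questionnaires"))
    quest = inject_questionnaires(participants, outcomes, spec, rng)
    return participants_frame(participants), outcomes, quest


def recovered_correlation(pframe: pd.DataFrame, outcomes: pd.DataFrame,
                          quest: pd.DataFrame,
                          target: CorrelationTarget) -> tuple[float, int]:
    """Sample Pearson r for one target on one cohort (pairwise complete)."""
    from scipy import stats as sps

    wide = outcomes.pivot(index="participant_id", columns="protocol_id",
                          values="threshold")
    wide.columns = [f"{c}_threshold" for c in wide.columns]
    merged = pframe.set_index("participant_id").join(wide).join(
        quest.set_index("participant_id"))
    mask = mask_for(target.mask, merged["group"])
    col = f"{target.instrument}_{target.subscale}"
    pair = merged.loc[mask, [target.metric, col]].dropna()
    if len(pair) < 3:
        raise InjectionError(f"fewer than 3 complete pairs for {target}")
    r, _ = sps.pearsonr(pair[target.metric], pair[col])
    return float(r), len(pair)


def recover_correlations(spec: CohortSpec,
                         targets: Sequence[CorrelationTarget],
                         n_replicates: int, seed: int,
                         protocols: Iterable[str] | None = None
                         ) -> dict[CorrelationTarget, tuple[float, int]]:
    """Mean recovered sample r per target over replicate cohorts."""
    sums = {t: [] for t in targets}
    ns = {t: 0 for t in targets}
    for k in range(n_replicates):
        pframe, outcomes, quest = replicate_cohort(
            spec, derive_seed(seed, "corr", k), protocols)
        for t in targets:
            r, n = recovered_correlation(pframe, outcomes, quest, t)
            sums[t].append(r)
            ns[t] = n
    return {t: (float(np.mean(sums[t])), ns[t]) for t in targets}


def seq_pairwise_min(quest: pd.DataFrame) -> float:
    """Minimum pairwise r among the three SEQ composite scores."""
    from scipy import stats as sps

    cols = ["seq_total_hyper", "seq_total_hypo", "seq_total_seeking"]
    rs = []
    for i in range(3):
        for j in range(i + 1, 3):
            pair = quest[[cols[i], cols[j]]].dropna()
            rs.append(sps.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])[0])
    return float(min(rs))


def questionnaires_long(wide: pd.DataFrame) -> pd.DataFrame:
    """Melt the wide questionnaire table to participant/scale/score rows."""
    long = wide.melt(id_vars="participant_id", var_name="scale",
                     value_name="score").dropna(subset=["score"])
    return long.reset_index(drop=True)


# ---------------------------------------------------------------------------
# spec (de)serialization

def spec_to_dict(spec: CohortSpec) -> dict:
    d = {
        "group_sizes": dict(spec.group_sizes),
        "age_mean_sd": {g: list(v) for g, v in spec.age_mean_sd.items()},
        "effect_sizes": {p: dict(v) for p, v in spec.effect_sizes.items()},
        "baseline_theta": {p: list(v) for p, v in spec.baseline_theta.items()},
        "sigma": dict(spec.sigma),
        "age_slope": dict(spec.age_slope),
        "lapse_range": list(spec.lapse_range),
        "rt_median_ms": spec.rt_median_ms,
        "rt_median_log_sd": spec.rt_median_log_sd,
        "rt_spread": spec.rt_spread,
        "toj_completion_fraction": spec.toj_completion_fraction,
        "inflation": {f"{p}|{g}": v for (p, g), v in spec.inflation.items()},
        "correlation_targets": [
            {"metric": t.metric, "instrument": t.instrument,
             "subscale": t.subscale, "r": t.r, "mask": t.mask}
            for t in spec.correlation_targets],
        "seq_shared_loading": spec.seq_shared_loading,
        "score_mean": spec.score_mean,
        "score_sd": spec.score_sd,
    }
    return d


def spec_from_dict(d: dict) -> CohortSpec:
    kwargs = dict(d)
    if "age_mean_sd" in kwargs:
        kwargs["age_mean_sd"] = {g: tuple(v)
                                 for g, v in kwargs["age_mean_sd"].items()}
    if "baseline_theta" in kwargs:
        kwargs["baseline_theta"] = {
            p: tuple(v) for p, v in kwargs["baseline_theta"].items()}
    if "lapse_range" in kwargs:
        kwargs["lapse_range"] = tuple(kwargs["lapse_range"])
    if "inflation" in kwargs:
        kwargs["inflation"] = {tuple(k.split("|")): v
                               for k, v in kwargs["inflation"].items()}
    if "correlation_targets" in kwargs:
        kwargs["correlation_targets"] = tuple(
            CorrelationTarget(**t) for t in kwargs["correlation_targets"])
    return CohortSpec(**kwargs)


def save_spec(spec: CohortSpec, path) -> None:
    import yaml
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def load_spec(path) -> CohortSpec:
    import yaml
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))
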