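"""Synthetic multi-series time-course expression data with known regulation.

The generator emulates the structure of multi-tissue circadian compendia:
several independent time series ("series" = tissues or subjects) sampled over
one or two days, with most of the total variance coming from between-series
baseline offsets rather than from within-series dynamics.

Ground truth is planted mechanistically.  Each regulator has a latent
activity curve (a random periodic waveform with tissue-specific phase,
amplitude and shape for cyclic designs; a smoothed random walk per series
otherwise).  Each target integrates that activity through a production-
degradation ODE::

    dY/dt = k * f(A(t)) - delta * Y

with ``f`` a cooperative (Hill) activation or repression.  A slowly degraded
target (small ``delta``) accumulates: its *level* is a lagged, smoothed echo
of the regulator, weakly correlated with it, while its *rate of change*
stays tightly coupled to when the regulator crosses its activation
threshold — exactly the regime in which rate-change features carry
information that raw expression levels do not.  Decoy genes follow
independent smooth noise.  Observation noise and per-gene per-series
baseline offsets are added to every gene at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GoldStandard

__all__ = [
    "SimulationConfig",
    "Activity",
    "SyntheticDataset",
    "simulate_regulator",
    "integrate_target",
    "simulate_targets",
    "assemble_dataset",
]


@dataclass
class SimulationConfig:
    """Study-design and kinetic parameters for the generator.

    Defaults describe a multi-tissue circadian compendium scaled to desk
    size: 6 series sampled every 2 h over 48 h (24 samples each, cyclic with
    a 24 h period), 5 strongly rhythmic regulators (RMS amplitude 5 against
    a mean baseline of 10, a ~3-4 fold swing) with 20 targets apiece, 100
    decoy genes, slow target degradation (half-lives of ~5-14 h against a
    24 h rhythm, so target levels lag and flatten), and between-series
    offsets whose SD (3.0) dominates the targets' within-series signal SD
    (~1) the way tissue baselines dominate daily variation.
    """

    n_series: int = 6
    samples_per_series: int = 24
    interval: float = 2.0          # hours between samples (even sampling)
    sampling: str = "even"         # "even" | "uneven"
    jitter: float = 0.3            # fraction of interval, uneven mode
    cyclic: bool = True
    period: float = 24.0           # hours, cyclic mode
    n_regulators: int = 5
    n_targets_per_regulator: int = 20
    n_decoy_genes: int = 100
    degradation_range: tuple = (0.05, 0.15)   # 1/h
    regulation_strength: float = 1.0          # k, expression units/h at saturation
    hill_coefficient: float = 4.0             # cooperativity of f(regulator)
    repressor_fraction: float = 0.0
    noise_sd: float = 0.2          # observation noise, expression units
    offset_sd: float = 3.0         # between-series baseline SD, expression units
    baseline: float = 10.0         # mean per-gene baseline, keeps values positive
    amplitude: float = 5.0         # regulator activity RMS (expression units)
    phase_jitter_sd: float = 2.0   # hours; per-series phase shift of each regulator
    amplitude_jitter: float = 0.3  # fractional per-series amplitude variation
    waveform_jitter: float = 1.2   # relative RMS of series-specific waveform wiggles
    n_harmonics: int = 4           # harmonics of the period in cyclic activities
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_series", "samples_per_series", "n_regulators",
            "n_targets_per_regulator",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_decoy_genes < 0 or self.noise_sd < 0 or self.offset_sd < 0:
            raise ValueError("counts and noise SDs must be non-negative")
        if self.sampling not in ("even", "uneven"):
            raise ValueError(f"unknown sampling mode {self.sampling!r}")


class Activity:
    """A latent regulator activity curve, evaluable at arbitrary times.

    Cyclic curves are random smooth periodic waveforms — a short Fourier
    series (harmonics of the configured period, complex coefficients) on a
    positive offset; aperiodic curves interpolate a smoothed random walk.
    """

    def __init__(self, kind, params):
        self.kind = kind
        self.params = params

    def at(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        p = self.params
        if self.kind == "fourier":
            w = 2 * np.pi / p["period"]
            coeffs = p["coeffs"]  # complex, harmonic k = index + 1
            k = np.arange(1, len(coeffs) + 1)
            phases = np.exp(1j * np.outer(k, w * t))
            return p["base"] + np.real(coeffs @ phases)
        return np.interp(t, p["grid"], p["values"])


def _random_walk_activity(rng, t_min, t_max, amplitude, floor=0.2) -> Activity:
    """Smooth aperiodic activity: Gaussian-filtered random walk, kept positive."""
    n = 200
    grid = np.linspace(t_min - 1.0, t_max + 1.0, n)
    walk = np.cumsum(rng.normal(0.0, 1.0, size=n))
    kernel = np.exp(-0.5 * (np.arange(-15, 16) / 5.0) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(walk, kernel, mode="same")
    smooth -= smooth.min()
    rng_span = smooth.max() if smooth.max() > 0 else 1.0
    values = floor + amplitude * 2.0 * smooth / rng_span
    return Activity("walk", {"grid": grid, "values": values})


def _fourier_coeffs(rng, n_harmonics: int, rms: float, decay: float = 1.5) -> np.ndarray:
    """Random complex Fourier coefficients with 1/k^decay energy, given RMS."""
    k = np.arange(1, n_harmonics + 1, dtype=float)
    c = (rng.normal(size=n_harmonics) + 1j * rng.normal(size=n_harmonics)) / k**decay
    if rms == 0:
        return np.zeros(n_harmonics, dtype=complex)
    norm = np.sqrt((np.abs(c) ** 2).sum() / 2.0)
    return c * (rms / norm) if norm > 0 else c


def simulate_regulator(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> list[dict]:
    """Draw latent activity curves: one per regulator per series.

    Cyclic mode: each regulator has a global periodic waveform — a random
    Fourier series over ``n_harmonics`` harmonics of the period with RMS
    U(0.6, 1.0) x ``cfg.amplitude`` — which every series expresses with its
    own phase shift (SD ``phase_jitter_sd`` hours), amplitude factor
    (U(1 - j, 1 + j), j = ``amplitude_jitter``) and a series-specific
    waveform wiggle (relative RMS ``waveform_jitter``).  This emulates the
    tissue-specific phases, amplitudes and waveforms of multi-tissue
    circadian data, and it is what makes the causal regulator identifiable
    among same-period rhythms: a pure shared sinusoid would be
    indistinguishable from any phase-shifted competitor.  Each series curve
    is strictly positive and exactly periodic.  Aperiodic mode: an
    independent smoothed random walk per series.

    Returns a list (over regulators) of dicts mapping series id -> Activity.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    t_max = cfg.samples_per_series * cfg.interval
    series_ids = [f"S{s + 1}" for s in range(cfg.n_series)]
    w_jit = 2 * np.pi * cfg.phase_jitter_sd / cfg.period
    grid = np.linspace(0.0, cfg.period, 257)
    out = []
    for r in range(cfg.n_regulators):
        curves = {}
        if cfg.cyclic:
            rms = cfg.amplitude * rng.uniform(0.6, 1.0)
            base_coeffs = _fourier_coeffs(rng, cfg.n_harmonics, rms)
            # peak phases tile the cycle (with jitter), as circadian
            # regulators do; coincident-phase regulators would be
            # interchangeable up to their weaker harmonics
            slot = 2 * np.pi * (r + rng.uniform(-0.2, 0.2)) / cfg.n_regulators
            base_coeffs[0] = np.abs(base_coeffs[0]) * np.exp(1j * slot)
            k = np.arange(1, cfg.n_harmonics + 1)
            for sid in series_ids:
                shift = rng.normal(0.0, w_jit)
                u = rng.uniform(1 - cfg.amplitude_jitter, 1 + cfg.amplitude_jitter)
                wiggle = _fourier_coeffs(rng, cfg.n_harmonics, rms * cfg.waveform_jitter)
                coeffs = u * base_coeffs * np.exp(1j * k * shift) + wiggle
                a = Activity(
                    "fourier",
                    {"period": cfg.period, "coeffs": coeffs, "base": 0.0},
                )
                a.params["base"] = 0.2 - min(0.0, float(a.at(grid).min()))
                curves[sid] = a
        else:
            for sid in series_ids:
                curves[sid] = _random_walk_activity(rng, 0.0, t_max, cfg.amplitude)
        out.append(curves)
    return out


def _sample_times(cfg: SimulationConfig, rng: np.random.Generator) -> dict:
    times = {}
    for s in range(cfg.n_series):
        t = np.arange(cfg.samples_per_series, dtype=float) * cfg.interval
        if cfg.sampling == "uneven":
            jit = rng.uniform(-cfg.jitter, cfg.jitter, size=len(t)) * cfg.interval
            jit[0] = abs(jit[0])  # keep the series start at/after 0
            t = np.sort(t + jit)
            # enforce strictly increasing times despite jitter collisions
            t = np.maximum.accumulate(t + 1e-9 * np.arange(len(t)))
        times[f"S{s + 1}"] = t
    return times


def _hill(a: np.ndarray, K: float, mode: str, h: float = 1.0) -> np.ndarray:
    r = (a / K) ** h
    if mode == "repression":
        return 1.0 / (1.0 + r)
    return r / (1.0 + r)


def integrate_target(
    activity: Activity,
    times: np.ndarray,
    *,
    k: float,
    delta: float,
    K: float,
    mode: str = "activation",
    hill: float = 1.0,
    max_step_fraction: float = 0.1,
) -> np.ndarray:
    """Integrate dY/dt = k f(A(t)) - delta Y over one series' time span.

    Explicit Euler with automatic sub-stepping: the step never exceeds
    ``max_step_fraction / delta`` (stability) or a quarter of the smallest
    sampling gap (resolution).  The trajectory starts at the quasi-steady
    state of the first time point, avoiding an arbitrary transient.
    """
    if delta <= 0:
        raise ValueError("degradation rate must be positive")
    times = np.asarray(times, dtype=float)
    dt_max = min(max_step_fraction / delta, np.diff(times).min() / 4.0)
    y = k * _hill(activity.at(times[:1]), K, mode, hill)[0] / delta
    out = np.empty(len(times))
    out[0] = y
    for i in range(len(times) - 1):
        span = times[i + 1] - times[i]
        n_sub = max(1, int(np.ceil(span / dt_max)))
        dt = span / n_sub
        t = times[i]
        for _ in range(n_sub):
            y += dt * (k * _hill(activity.at(np.array([t]))[0], K, mode, hill) - delta * y)
            t += dt
        out[i + 1] = y
    return out


def simulate_targets(
    activities: list[Activity],
    times_by_series: dict,
    assignments: pd.DataFrame,
    cfg: SimulationConfig,
) -> pd.DataFrame:
    """Noiseless target trajectories for every (target, series).

    ``assignments`` has one row per target gene with columns ``regulator``
    (index into ``activities``), ``k``, ``delta``, ``K``, ``mode``.  Each
    target integrates its own series' regulator curve.  Targets with
    ``k == 0`` evolve independently of any regulator (pure decay to the
    baseline production 0) and are excluded from the returned ground truth
    by :func:`assemble_dataset`.
    """
    cols = []
    names = []
    for series_id, times in times_by_series.items():
        block = np.empty((len(assignments), len(times)))
        for i, (_, row) in enumerate(assignments.iterrows()):
            block[i] = integrate_target(
                activities[int(row["regulator"])][series_id],
                times,
                k=float(row["k"]),
                delta=float(row["delta"]),
                K=float(row["K"]),
                mode=str(row["mode"]),
                hill=float(cfg.hill_coefficient),
            )
        cols.append(block)
        names.extend(_sample_ids(series_id, times))
    return pd.DataFrame(np.hstack(cols), index=assignments.index, columns=names)


def _sample_ids(series_id: str, times: np.ndarray) -> list[str]:
    return [f"{series_id}_{i:03d}" for i in range(len(times))]


@dataclass
class SyntheticDataset:
    """Generated expression data plus its ground truth."""

    expression: ExpressionMatrix
    true_edges: GoldStandard
    regulators: list
    params: dict = field(default_factory=dict)


def assemble_dataset(cfg: SimulationConfig | None = None) -> SyntheticDataset:
    """Build a complete dataset: regulators, targets, decoys, noise, offsets.

    All randomness flows from ``cfg.seed`` through named substreams
    (regulators / targets / decoys / noise+offsets), so any one component is
    reproducible independently of the others.
    """
    cfg = cfg or SimulationConfig()
    root = np.random.SeedSequence(cfg.seed)
    ss_reg, ss_tgt, ss_dec, ss_noise = root.spawn(4)
    rng_reg = np.random.default_rng(ss_reg)
    rng_tgt = np.random.default_rng(ss_tgt)
    rng_dec = np.random.default_rng(ss_dec)
    rng_noise = np.random.default_rng(ss_noise)

    activities = simulate_regulator(cfg, rng_reg)
    times_by_series = _sample_times(cfg, rng_reg)

    # target kinetic parameters
    rows = []
    grid = np.linspace(0, cfg.samples_per_series * cfg.interval, 97)
    for r in range(cfg.n_regulators):
        med_act = float(
            np.median(np.concatenate([c.at(grid) for c in activities[r].values()]))
        )
        for j in range(cfg.n_targets_per_regulator):
            mode = (
                "repression"
                if rng_tgt.random() < cfg.repressor_fraction
                else "activation"
            )
            rows.append(
                {
                    "gene": f"TG{r + 1:02d}_{j + 1:02d}",
                    "regulator": r,
                    "regulator_gene": f"TF{r + 1:02d}",
                    "k": cfg.regulation_strength * rng_tgt.uniform(0.8, 1.2),
                    "delta": rng_tgt.uniform(*cfg.degradation_range),
                    "K": med_act * rng_tgt.uniform(0.7, 1.4),
                    "mode": mode,
                }
            )
    assignments = pd.DataFrame(rows).set_index("gene")

    target_traj = simulate_targets(activities, times_by_series, assignments, cfg)
    # a target with zero regulation strength has no planted edge; give it
    # independent basal smooth dynamics so it is statistically exchangeable
    # with decoy genes rather than collapsing to flat zero production
    null_targets = assignments.index[assignments["k"] == 0]
    if len(null_targets):
        for gene in null_targets:
            curve = _random_walk_activity(
                rng_tgt, 0.0, cfg.samples_per_series * cfg.interval, cfg.amplitude
            )
            row = np.concatenate(
                [curve.at(times) for times in times_by_series.values()]
            )
            target_traj.loc[gene] = row

    # regulator mRNA follows its activity; decoys are independent smooth noise
    sample_ids, design_rows = [], []
    reg_blocks, dec_blocks = [], []
    decoy_curves = [
        _random_walk_activity(
            rng_dec, 0.0, cfg.samples_per_series * cfg.interval, cfg.amplitude
        )
        for _ in range(cfg.n_decoy_genes)
    ]
    for series_id, times in times_by_series.items():
        ids = _sample_ids(series_id, times)
        sample_ids.extend(ids)
        for sid, t in zip(ids, times):
            design_rows.append(
                {"sample_id": sid, "series_id": series_id, "time": t, "cyclic": cfg.cyclic}
            )
        reg_blocks.append(np.vstack([a[series_id].at(times) for a in activities]))
        if cfg.n_decoy_genes:
            dec_blocks.append(np.vstack([c.at(times) for c in decoy_curves]))

    reg_names = [f"TF{r + 1:02d}" for r in range(cfg.n_regulators)]
    dec_names = [f"DC{d + 1:03d}" for d in range(cfg.n_decoy_genes)]
    parts = [
        pd.DataFrame(np.hstack(reg_blocks), index=reg_names, columns=sample_ids),
        target_traj.loc[:, sample_ids],
    ]
    if cfg.n_decoy_genes:
        parts.append(
            pd.DataFrame(np.hstack(dec_blocks), index=dec_names, columns=sample_ids)
        )
    clean = pd.concat(parts, axis=0)

    n_genes, n_samples = clean.shape
    series_of = [row["series_id"] for row in design_rows]
    series_codes = pd.Categorical(series_of).codes
    baselines = cfg.baseline * rng_noise.uniform(0.8, 1.2, size=(n_genes, 1))
    offsets = rng_noise.normal(0.0, cfg.offset_sd, size=(n_genes, cfg.n_series))
    noise = rng_noise.normal(0.0, cfg.noise_sd, size=(n_genes, n_samples))
    values = clean.to_numpy() + baselines + offsets[:, series_codes] + noise
    np.clip(values, 0.0, None, out=values)

    design = pd.DataFrame(design_rows).set_index("sample_id")
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=clean.index, columns=sample_ids), design
    )

    positives: dict = {r: set() for r in reg_names}
    for gene, row in assignments.iterrows():
        if row["k"] > 0:
            positives[row["regulator_gene"]].add(gene)
    truth = GoldStandard(positives, universe=list(clean.index))

    params = {
        "targets": assignments,
        "times_by_series": times_by_series,
        "config": cfg,
    }
    return SyntheticDataset(
        expression=expr, true_edges=truth, regulators=reg_names, params=params
    )
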