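"""Synthetic 2-group x 2-condition cohort with known ground-truth effects.

Emulates the study's three input kinds so every downstream stage is testable
without participant data:

* **COP trajectories** — a mean-reverting (Ornstein–Uhlenbeck) planar random
  walk per trial, Euler-discretized at the platform rate: bounded-variance
  stationary sway, with per-axis diffusion controlling sway magnitude.
* **fNIRS recordings** — latent ROI signals with covariance
  ``Sigma = I + coupling * A`` induced by a network template (small-world or
  degree-preserving-randomized ring lattice), copied to each ROI's channels
  plus channel noise, physiological oscillations (Mayer/respiratory/
  cardiac), drift and optional motion spikes, then pushed through the
  forward modified Beer–Lambert model to raw two-wavelength intensities.
* **cohort metadata** — demographics drawn per group from configurable
  summaries.

Group-by-condition effect structure is injected through per-cell multipliers
on COP diffusion (sway magnitude) and per-cell degree-preserving
randomization of the network template (topology). All randomness derives
from a master seed via per-unit seed sequences, so identical designs are
bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import signal as _signal

from .fnirs_preprocess import OpticalRecording, hemoglobin_to_od
from .posturography import CopTrial, write_cop_csv
from .roi_connectivity import ROI_ORDER, ChannelMap, default_channel_map
from .network_topology import ring_lattice, rewire_degree_preserving

__all__ = [
    "CopGenParams",
    "NetworkTemplate",
    "NoiseSpec",
    "CellEffect",
    "CohortDesign",
    "CohortDataset",
    "generate_cop_trial",
    "generate_network_template",
    "generate_fnirs_recording",
    "generate_cohort",
    "write_cohort",
]

#: AR(1) smoothing time constant of the latent ROI processes (s).
LATENT_TAU_S = 0.1

#: ΔHbR is modelled as this fraction of -ΔHbO (typical anticorrelation).
HBR_RATIO = 0.4


def _seed_seq(master_seed: int, *key: int) -> np.random.SeedSequence:
    """Independent, reproducible stream for one (participant, condition,
    trial, stage) unit."""
    return np.random.SeedSequence(entropy=(int(master_seed), *map(int, key)))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# COP generation


@dataclass(frozen=True)
class CopGenParams:
    """Ornstein–Uhlenbeck sway parameters.

    ``x <- x - restoring_rate*x*dt + diffusion*sqrt(dt)*eps`` per axis;
    stationary RMS is ``diffusion / sqrt(2*restoring_rate)``. Defaults give
    ML/AP RMS of roughly 3.3 / 5.8 mm, the magnitude of quiet standing.
    """

    restoring_rate: float = 1.0  # 1/s
    diffusion: tuple[float, float] = (4.7, 8.2)  # mm/sqrt(s), (ML, AP)
    sampling_rate: float = 1000.0
    duration: float = 30.0

    def __post_init__(self):
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be positive")
        if self.restoring_rate < 0 or any(d < 0 for d in self.diffusion):
            raise ValueError("restoring_rate and diffusion must be >= 0")

    def scaled(self, diffusion_factor: float) -> "CopGenParams":
        return CopGenParams(
            restoring_rate=self.restoring_rate,
            diffusion=tuple(d * diffusion_factor for d in self.diffusion),
            sampling_rate=self.sampling_rate, duration=self.duration)


def generate_cop_trial(params: CopGenParams, seed, **trial_kwargs) -> CopTrial:
    """One stationary OU trial; exact AR(1) recursion via ``lfilter``."""
    rng = _rng(seed)
    n = int(round(params.duration * params.sampling_rate))
    dt = 1.0 / params.sampling_rate
    a = 1.0 - params.restoring_rate * dt
    if not 0 <= a <= 1:
        raise ValueError("restoring_rate too large for this sampling step")
    axes = []
    for d in params.diffusion:
        b = d * np.sqrt(dt)
        w = rng.standard_normal(n)
        x = _signal.lfilter([1.0], [1.0, -a], b * w)
        if a < 1 and b > 0:  # start in the stationary distribution
            x0 = rng.normal(0.0, b / np.sqrt(1 - a * a))
            x = x + x0 * a ** np.arange(1, n + 1)
        axes.append(x)
    return CopTrial(sampling_rate=params.sampling_rate,
                    ml=axes[0], ap=axes[1], **trial_kwargs)


# ---------------------------------------------------------------------------
# Network templates


@dataclass(frozen=True)
class NetworkTemplate:
    n_nodes: int
    kind: str
    base_degree: int
    rewire_prob: float
    coupling: float
    adjacency: np.ndarray

    def __post_init__(self):
        if self.n_nodes < 3:
            raise ValueError("need at least 3 nodes")
        if not 0 <= self.rewire_prob <= 1:
            raise ValueError("rewire_prob must lie in [0, 1]")
        if self.coupling < 0:
            raise ValueError("coupling must be >= 0")

    def covariance(self) -> np.ndarray:
        """Latent ROI covariance ``I + coupling * A``; must be positive
        definite."""
        sigma = np.eye(self.n_nodes) + self.coupling * self.adjacency.astype(float)
        if np.linalg.eigvalsh(sigma)[0] <= 1e-9:
            raise ValueError(
                f"coupling {self.coupling} makes the implied covariance "
                "non-positive-definite for this adjacency")
        return sigma


def generate_network_template(kind: str, n_nodes: int = 10,
                              base_degree: int = 4, rewire_prob: float = 0.1,
                              seed=None, coupling: float = 0.24
                              ) -> NetworkTemplate:
    """Small-world (Watts–Strogatz) or degree-preserving-randomized lattice.

    ``randomized`` starts from the same ring lattice and applies 20x-edges
    double-edge swaps, so its degree sequence equals the lattice's.
    """
    if base_degree % 2 != 0 or not 0 < base_degree < n_nodes:
        raise ValueError("base_degree must be even and < n_nodes")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    if kind == "smallworld":
        nx_seed = int(ss.generate_state(1)[0])
        g = nx.watts_strogatz_graph(n_nodes, base_degree, rewire_prob, seed=nx_seed)
        adj = nx.to_numpy_array(g, dtype=bool)
    elif kind == "randomized":
        lattice = ring_lattice(n_nodes, base_degree)
        n_edges = int(lattice.sum()) // 2
        adj = rewire_degree_preserving(lattice, n_swaps=20 * n_edges,
                                       seed=np.random.default_rng(ss))
    else:
        raise ValueError(f"unknown template kind {kind!r}")
    return NetworkTemplate(n_nodes=n_nodes, kind=kind, base_degree=base_degree,
                           rewire_prob=rewire_prob, coupling=coupling,
                           adjacency=adj)


def randomize_template(template: NetworkTemplate, amount: float, seed
                       ) -> NetworkTemplate:
    """Partially randomize a template: ``amount`` in [0, 1] scales the number
    of degree-preserving double-edge swaps (1.0 = 10x edge count)."""
    if not 0 <= amount <= 1:
        raise ValueError("randomization amount must lie in [0, 1]")
    if amount == 0:
        return template
    n_edges = int(template.adjacency.sum()) // 2
    n_swaps = int(round(amount * 10 * n_edges))
    adj = rewire_degree_preserving(template.adjacency, n_swaps=n_swaps,
                                   seed=_rng(seed))
    return NetworkTemplate(n_nodes=template.n_nodes, kind=template.kind,
                           base_degree=template.base_degree,
                           rewire_prob=template.rewire_prob,
                           coupling=template.coupling, adjacency=adj)


# ---------------------------------------------------------------------------
# fNIRS forward synthesis


@dataclass(frozen=True)
class NoiseSpec:
    """Physiological and instrumental noise for the optical channels.

    Oscillations are (frequency Hz, amplitude) pairs in units of the latent
    signal SD, with independent phase per channel: Mayer waves (~0.1 Hz),
    respiration (~0.3 Hz) and cardiac pulsation (~1.0 Hz) by default.
    ``global_signal_sd`` adds a systemic in-band component shared by every
    channel — the global physiological baseline that makes real fNIRS
    correlations predominantly positive. Drift and spikes act on optical
    density (motion affects both wavelengths); spike amplitude is in
    multiples of the channel OD SD.
    """

    oscillations: tuple = ((0.1, 0.3), (0.3, 0.4), (1.0, 0.6))
    global_signal_sd: float = 0.6
    channel_noise_sd: float = 0.6
    drift_od_per_min_sd: float = 0.01
    spike_rate_per_min: float = 0.5
    spike_amplitude_sd: float = 12.0

    def __post_init__(self):
        for f, a in self.oscillations:
            if a < 0:
                raise ValueError("oscillation amplitudes must be >= 0")
            if f >= 5.5:
                raise ValueError(
                    f"oscillation at {f} Hz exceeds the 11 Hz Nyquist")
        if min(self.global_signal_sd, self.channel_noise_sd,
               self.drift_od_per_min_sd, self.spike_rate_per_min,
               self.spike_amplitude_sd) < 0:
            raise ValueError("noise parameters must be >= 0")

    @classmethod
    def clean(cls) -> "NoiseSpec":
        """No noise at all — for contract tests."""
        return cls(oscillations=(), global_signal_sd=0.0,
                   channel_noise_sd=0.0, drift_od_per_min_sd=0.0,
                   spike_rate_per_min=0.0, spike_amplitude_sd=0.0)


def _latent_roi_signals(template: NetworkTemplate, n_t: int, dt: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-variance AR(1)-smoothed Gaussian processes mixed to covariance
    ``I + coupling*A``."""
    sigma = template.covariance()
    chol = np.linalg.cholesky(sigma)
    phi = np.exp(-dt / LATENT_TAU_S)
    w = rng.standard_normal((template.n_nodes, n_t))
    latent = _signal.lfilter([np.sqrt(1 - phi * phi)], [1.0, -phi], w, axis=1)
    return chol @ latent


def generate_fnirs_recording(template: NetworkTemplate, noise: NoiseSpec,
                             channel_map: ChannelMap, duration: float = 600.0,
                             seed=None, sampling_rate: float = 11.0,
                             hbo_scale_um: float = 0.5,
                             source_detector_distance_cm: float = 3.0
                             ) -> OpticalRecording:
    """Forward-synthesize a raw two-wavelength recording.

    Every channel inherits its ROI's latent signal plus independent channel
    noise and oscillations (in the hemodynamic domain), is converted to
    optical density by the forward MBLL, then receives drift and motion
    spikes (in the OD domain) before exponentiation to intensity.
    """
    if template.n_nodes != len(ROI_ORDER):
        raise ValueError("template must have one node per ROI")
    rng = _rng(seed if not isinstance(seed, np.random.SeedSequence) else seed)
    n_t = int(round(duration * sampling_rate))
    dt = 1.0 / sampling_rate
    roi_sig = _latent_roi_signals(template, n_t, dt, rng)

    roi_index = {roi: k for k, roi in enumerate(ROI_ORDER)}
    channels = sorted(channel_map.assignment)
    ch_roi = np.array([roi_index[channel_map.assignment[ch]] for ch in channels])
    n_ch = len(channels)

    sig = roi_sig[ch_roi].copy()
    if noise.global_signal_sd > 0:
        phi = np.exp(-dt / LATENT_TAU_S)
        g = _signal.lfilter([np.sqrt(1 - phi * phi)], [1.0, -phi],
                            rng.standard_normal(n_t))
        sig += noise.global_signal_sd * g[None, :]
    if noise.channel_noise_sd > 0:
        sig += noise.channel_noise_sd * rng.standard_normal((n_ch, n_t))
    t = np.arange(n_t) * dt
    for freq, amp in noise.oscillations:
        phase = rng.uniform(0, 2 * np.pi, size=n_ch)
        sig += amp * np.sin(2 * np.pi * freq * t[None, :] + phase[:, None])

    hbo = hbo_scale_um * sig
    hbr = -HBR_RATIO * hbo
    od = hemoglobin_to_od(hbo, hbr, source_detector_distance_cm)

    if noise.drift_od_per_min_sd > 0:
        slopes = rng.normal(0.0, noise.drift_od_per_min_sd, size=(n_ch, 2))
        od += slopes[:, :, None] * (t / 60.0)[None, None, :]
    if noise.spike_rate_per_min > 0 and noise.spike_amplitude_sd > 0:
        od_sd = od.std(axis=2)  # (ch, wavelength)
        n_spikes = rng.poisson(noise.spike_rate_per_min * duration / 60.0,
                               size=n_ch)
        for ch in range(n_ch):
            for _ in range(n_spikes[ch]):
                pos = rng.integers(0, n_t)
                width = int(rng.integers(2, 5))
                sign = rng.choice([-1.0, 1.0])
                sl = slice(pos, min(pos + width, n_t))
                od[ch, :, sl] += (sign * noise.spike_amplitude_sd
                                  * od_sd[ch][:, None])
    intensity = 10.0 ** (-od)  # baseline intensity 1.0 a.u.
    return OpticalRecording(intensity=intensity, sampling_rate=sampling_rate,
                            source_detector_distance_cm=source_detector_distance_cm)


# ---------------------------------------------------------------------------
# Cohort


@dataclass(frozen=True)
class CellEffect:
    """Ground-truth manipulation of one group x condition cell."""

    diffusion: float = 1.0  # multiplies COP diffusion on both axes
    randomization: float = 0.0  # 0 = base template, 1 = fully randomized

    def __post_init__(self):
        if self.diffusion < 0 or not 0 <= self.randomization <= 1:
            raise ValueError("invalid cell effect")


def default_cell_effects() -> dict:
    """Effect pattern mirroring the study: sway grows and topology
    randomizes with eyes closed, most strongly in the MCI group."""
    return {
        ("MCI", "open"): CellEffect(1.0, 0.1),
        ("MCI", "closed"): CellEffect(1.3, 0.7),
        ("CN", "open"): CellEffect(1.0, 0.0),
        ("CN", "closed"): CellEffect(1.17, 0.25),
    }


def null_cell_effects(groups=("MCI", "CN"), conditions=("open", "closed")) -> dict:
    return {(g, c): CellEffect(1.0, 0.0) for g in groups for c in conditions}


#: Per-group demographic sampling parameters (age yr, height cm, weight kg,
#: P(male)) typical of community-dwelling older adults in the two groups.
DEFAULT_DEMOGRAPHICS = {
    "MCI": {"age": (67.26, 2.77), "height": (163.00, 7.69),
            "weight": (68.05, 9.25), "male_p": 12 / 34},
    "CN": {"age": (66.82, 3.30), "height": (160.03, 6.25),
           "weight": (64.75, 7.59), "male_p": 6 / 34},
}


@dataclass(frozen=True)
class CohortDesign:
    n_per_group: int = 34
    groups: tuple = ("MCI", "CN")
    conditions: tuple = ("open", "closed")
    trials_per_condition: int = 3
    cop_params: CopGenParams = field(default_factory=CopGenParams)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    coupling: float = 0.24
    template_base_degree: int = 4
    template_rewire_prob: float = 0.05
    fnirs_duration_s: float = 600.0
    subject_sd: float = 0.25  # lognormal sd of per-subject diffusion factor
    subject_condition_sd: float = 0.15  # extra per-subject-per-condition sd
    cell_effects: dict = field(default_factory=default_cell_effects)
    demographics: dict = field(default_factory=lambda: dict(DEFAULT_DEMOGRAPHICS))
    with_fnirs: bool = True
    master_seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1 or self.trials_per_condition < 1:
            raise ValueError("counts must be positive")
        if len(self.groups) != 2 or len(self.conditions) != 2:
            raise ValueError("design is 2 groups x 2 conditions")
        for g in self.groups:
            for c in self.conditions:
                if (g, c) not in self.cell_effects:
                    raise ValueError(f"missing cell effect for {(g, c)}")


@dataclass(frozen=True)
class CohortDataset:
    design: CohortDesign
    participants: pd.DataFrame  # participant, group, sex, age, height, weight
    cop_trials: dict  # (participant, condition) -> [CopTrial, ...]
    fnirs: dict  # (participant, condition) -> OpticalRecording or None
    channel_map: ChannelMap

    @property
    def n_trials(self) -> int:
        return sum(len(v) for v in self.cop_trials.values())


def generate_cohort(design: CohortDesign) -> CohortDataset:
    """Deterministic cohort under ``design.master_seed``.

    Per participant and condition: ``trials_per_condition`` COP trials and
    (optionally) one fNIRS recording whose template is the participant's
    base small-world network, degree-preservingly randomized by the cell's
    ``randomization`` amount.
    """
    cmap = default_channel_map()
    participants = []
    cop_trials: dict = {}
    fnirs: dict = {}
    ms = design.master_seed
    pid_num = 0
    for g_idx, group in enumerate(design.groups):
        demo = design.demographics[group]
        for k in range(design.n_per_group):
            pid = f"{group}{k + 1:03d}"
            p_key = (g_idx, k)
            demo_rng = _rng(_seed_seq(ms, *p_key, 900))
            participants.append({
                "participant": pid, "group": group,
                "sex": "M" if demo_rng.random() < demo["male_p"] else "F",
                "age": round(float(demo_rng.normal(*demo["age"])), 1),
                "height_cm": round(float(demo_rng.normal(*demo["height"])), 1),
                "weight_kg": round(float(demo_rng.normal(*demo["weight"])), 1),
            })
            subj_rng = _rng(_seed_seq(ms, *p_key, 901))
            subj_factor = float(np.exp(subj_rng.normal(0.0, design.subject_sd)))
            base_template = generate_network_template(
                "smallworld", n_nodes=len(ROI_ORDER),
                base_degree=design.template_base_degree,
                rewire_prob=design.template_rewire_prob,
                seed=_seed_seq(ms, *p_key, 902), coupling=design.coupling)
            for c_idx, cond in enumerate(design.conditions):
                effect = design.cell_effects[(group, cond)]
                cond_rng = _rng(_seed_seq(ms, *p_key, c_idx, 903))
                cond_factor = float(np.exp(
                    cond_rng.normal(0.0, design.subject_condition_sd)))
                params = design.cop_params.scaled(
                    effect.diffusion * subj_factor * cond_factor)
                trials = [
                    generate_cop_trial(
                        params, _seed_seq(ms, *p_key, c_idx, tr),
                        condition=cond, trial_index=tr, participant_id=pid)
                    for tr in range(design.trials_per_condition)
                ]
                cop_trials[(pid, cond)] = trials
                if design.with_fnirs:
                    template = randomize_template(
                        base_template, effect.randomization,
                        _seed_seq(ms, *p_key, c_idx, 904))
                    fnirs[(pid, cond)] = generate_fnirs_recording(
                        template, design.noise, cmap,
                        duration=design.fnirs_duration_s,
                        seed=np.random.default_rng(
                            _seed_seq(ms, *p_key, c_idx, 905)))
                else:
                    fnirs[(pid, cond)] = None
            pid_num += 1
    return CohortDataset(design=design,
                         participants=pd.DataFrame(participants),
                         cop_trials=cop_trials, fnirs=fnirs, channel_map=cmap)


def write_cohort(dataset: CohortDataset, outdir) -> None:
    """COP trials and fNIRS recordings as CSV plus a cohort manifest."""
    from .fnirs_preprocess import write_intensity_csv

    out = Path(outdir)
    (out / "cop").mkdir(parents=True, exist_ok=True)
    dataset.participants.to_csv(out / "participants.csv", index=False)
    manifest = []
    for (pid, cond), trials in dataset.cop_trials.items():
        for trial in trials:
            name = f"cop/{pid}_{cond}_t{trial.trial_index}.csv"
            write_cop_csv(trial, out / name)
            manifest.append({"participant": pid, "condition": cond,
                             "kind": "cop", "trial": trial.trial_index,
                             "path": name})
    if any(rec is not None for rec in dataset.fnirs.values()):
        (out / "fnirs").mkdir(exist_ok=True)
        for (pid, cond), rec in dataset.fnirs.items():
            if rec is None:
                continue
            name = f"fnirs/{pid}_{cond}.csv"
            write_intensity_csv(rec, out / name)
            manifest.append({"participant": pid, "condition": cond,
                             "kind": "fnirs", "trial": -1, "path": name})
    pd.DataFrame(manifest).to_csv(out / "manifest.csv", index=False)
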