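"""Seeded synthetic biologger deployments with known ground truth.

Two generation levels, sharing one state-sequence simulator:

* **feature level** — 30-s window features drawn directly from the HMM's
  emission model (Normal log10 features, Bernoulli immersion). This is the
  reference study for parameter-recovery work, because the true emission
  parameters are known exactly.
* **signal level** — raw 10 Hz tri-axial acceleration and 1 Hz immersion
  voltages with the qualitative phenomenology of each state (near-constant
  gravity vector at rest, oscillatory surge/heave/sway when active, rhythmic
  low-frequency digging bursts with pauses while nesting, well-separated
  wet/dry voltage bands), for exercising the full pipeline end to end.

Everything is reproducible from one master seed; per-individual streams are
spawned from it so the study is byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .hmm import EmissionParams, TransitionStructure, make_default_spec
from .io import RawBurst, default_schema, write_axy_csv
from .states import STATE_NAMES, StateLabel

__all__ = [
    "IndividualConfig",
    "StateSignal",
    "SimConfig",
    "default_config",
    "raw_study_config",
    "simulate_states",
    "simulate_features",
    "simulate_sensors",
    "simulate_feature_study",
    "make_study",
]


@dataclass
class IndividualConfig:
    individual_id: str
    sex: str
    gravid: bool
    n_windows: int
    dropout_after_windows: int | None = None  # gap inserted after this many windows
    dropout_gap_s: float = 7200.0


@dataclass
class StateSignal:
    """Raw-signal phenomenology of one state.

    ``osc_amp_g`` are surge/heave/sway oscillation amplitudes; ``dig`` turns
    on the nesting rhythm (sawtooth bursts with pauses) instead of the
    sinusoidal gait.
    """

    pitch_mean_deg: float
    pitch_jitter_sd_deg: float
    osc_amp_g: tuple[float, float, float]
    osc_freq_hz: float
    noise_sd_g: float
    wet: bool
    dig: bool = False


def _default_signals() -> dict[str, StateSignal]:
    # Posture-drift and oscillation scales calibrated once so that the
    # realized window features of each state land near the default-spec
    # starting geometry (swimming/walking: high pitch variance and moderate
    # ODBA; resting: near-constant gravity vector; digging: large rhythmic
    # posture swings).
    return {
        "ActiveWater": StateSignal(0.0, 9.0, (0.045, 0.045, 0.035), 0.8, 0.010, wet=True),
        "ActiveLand": StateSignal(5.0, 9.0, (0.15, 0.14, 0.12), 1.2, 0.010, wet=False),
        "InactiveWater": StateSignal(0.0, 0.05, (0.0, 0.0, 0.0), 0.0, 0.006, wet=True),
        "InactiveLand": StateSignal(2.0, 0.05, (0.0, 0.0, 0.0), 0.0, 0.006, wet=False),
        "Nesting": StateSignal(12.0, 18.0, (0.42, 0.42, 0.0), 0.15, 0.010, wet=False, dig=True),
    }


def _default_tpm() -> np.ndarray:
    # Sticky diagonals chosen so mean dwell times and the stationary
    # occupancy match field-scale activity budgets (water-dominated, rare
    # active-on-land excursions, ~5% nesting for gravid females); zeros at
    # the forbidden cells.
    return np.array(
        [
            [0.970, 0.006, 0.024, 0.000, 0.000],
            [0.060, 0.830, 0.030, 0.040, 0.040],
            [0.030, 0.000, 0.970, 0.000, 0.000],
            [0.004, 0.010, 0.003, 0.977, 0.006],
            [0.000, 0.020, 0.000, 0.010, 0.970],
        ]
    )


def _default_emission() -> EmissionParams:
    # Means sit at the default-spec starting means; true SDs keep the same
    # relative pattern but scaled to a realistic well-separated within-state
    # spread (the starting SDs are deliberately broad search windows, not
    # state widths). Window-level immersion is near-deterministic: the
    # majority vote over 30 wet/dry seconds essentially never flips.
    return EmissionParams(
        varpitch_mean=np.array([-0.5, -0.5, -6.0, -6.0, 0.2]),
        varpitch_sd=0.3 * np.array([3.0, 2.0, 3.0, 2.0, 1.0]),
        odba_mean=np.array([-1.0, -0.5, -2.0, -2.0, -0.5]),
        odba_sd=0.3 * np.array([0.8, 1.0, 0.5, 0.5, 0.2]),
        immersion_prob=np.array([1 - 1e-4, 1e-4, 1 - 1e-4, 1e-4, 1e-4]),
    )


@dataclass
class SimConfig:
    """Study design and true parameters for a synthetic deployment."""

    individuals: list[IndividualConfig] = field(default_factory=list)
    tpm: np.ndarray = field(default_factory=_default_tpm)
    emission: EmissionParams = field(default_factory=_default_emission)
    signals: dict[str, StateSignal] = field(default_factory=_default_signals)
    structure: TransitionStructure = field(default_factory=lambda: make_default_spec()[1])
    voltage_wet_mean: float = 200.0
    voltage_dry_mean: float = 800.0
    voltage_sd: float = 30.0
    dig_burst_s: float = 8.0
    dig_pause_s: float = 4.0
    accel_hz: float = 10.0
    immersion_hz: float = 1.0
    window_s: float = 30.0
    range_g: float = 2.0
    quantize_bits: int | None = 8
    dwell_mode: str = "markov"  # or "explicit": lognormal dwell times
    dwell_lognorm_sigma: float = 1.0
    start_time: pd.Timestamp = pd.Timestamp("2023-05-15T06:00:00Z")
    seed: int = 20230515

    def __post_init__(self) -> None:
        self.tpm = np.asarray(self.tpm, dtype=float)
        self.validate_tpm()
        gap = self.voltage_dry_mean - self.voltage_wet_mean
        if gap < 6 * self.voltage_sd:
            raise ValueError("wet/dry voltage bands must be >= 6 noise SDs apart")

    def validate_tpm(self) -> None:
        if self.tpm.shape != (5, 5):
            raise ValueError("true TPM must be 5x5")
        if not np.allclose(self.tpm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("true TPM rows must sum to 1")
        for i, j in self.structure.forbidden:
            if self.tpm[i, j] != 0.0:
                raise ValueError(
                    f"true TPM has mass on forbidden transition "
                    f"{STATE_NAMES[i]}->{STATE_NAMES[j]}"
                )

    def scale_activity_contrast(self, factor: float) -> "SimConfig":
        """Shrink active-state oscillation amplitudes toward the inactive
        baseline by ``factor`` (1 = default separation, 0 = none)."""
        signals = {}
        for name, sig in self.signals.items():
            amps = tuple(a * factor for a in sig.osc_amp_g)
            signals[name] = replace(sig, osc_amp_g=amps)
        cfg = replace(self, signals=signals)
        return cfg


def default_config() -> SimConfig:
    """The default synthetic study: 8 individuals (5 F of which 3 gravid,
    3 M), 2,000 windows (~16.7 h) each."""
    ids = [
        ("SYN_001", "female", False),
        ("SYN_002", "male", False),
        ("SYN_003", "female", True),
        ("SYN_005", "female", False),
        ("SYN_006", "male", False),
        ("SYN_013", "male", False),
        ("SYN_016", "female", True),
        ("SYN_017", "female", True),
    ]
    individuals = [IndividualConfig(i, s, g, n_windows=2000) for i, s, g in ids]
    return SimConfig(individuals=individuals)


def raw_study_config() -> SimConfig:
    """Reduced-scale signal-level study: mixed deployment lengths and one
    mid-deployment battery dropout (the re-activated-logger pattern)."""
    cfg = default_config()
    lengths = [800, 760, 300, 160, 700, 140, 600, 800]
    for ind, n in zip(cfg.individuals, lengths):
        ind.n_windows = n
    cfg.individuals[6].dropout_after_windows = 240
    cfg.individuals[6].dropout_gap_s = 6 * 3600.0
    return cfg


# --------------------------------------------------------------------------
# state sequences


def _masked_tpm(tpm: np.ndarray, gravid: bool, structure: TransitionStructure) -> tuple[np.ndarray, np.ndarray]:
    s = structure.allowed_states(gravid)
    sub = tpm[np.ix_(s, s)]
    sub = sub / sub.sum(axis=1, keepdims=True)
    return s, sub


def _stationary(sub: np.ndarray) -> np.ndarray:
    k = sub.shape[0]
    A = np.vstack([sub.T - np.eye(k), np.ones((1, k))])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


def simulate_states(
    config: SimConfig,
    n_windows: int,
    gravid: bool,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Markov chain of 0-based state indices over 30-s steps.

    Non-gravid chains run on the Nesting-masked sub-chain and therefore
    never enter Nesting; forbidden transitions never occur by construction.
    With ``dwell_mode="explicit"`` dwell times are lognormal (median equal
    to the geometric mean dwell of the matching TPM row) instead of
    geometric — deliberately misspecified relative to the plain HMM.
    """
    config.validate_tpm()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s, sub = _masked_tpm(config.tpm, gravid, config.structure)
    k = len(s)
    pi = _stationary(sub)
    if config.dwell_mode == "markov":
        cum = np.cumsum(sub, axis=1)
        states = np.empty(n_windows, dtype=np.int64)
        u = rng.random(n_windows)
        cur = int(np.searchsorted(np.cumsum(pi), u[0]))
        states[0] = cur
        for t in range(1, n_windows):
            cur = int(np.searchsorted(cum[cur], u[t]))
            states[t] = cur
        return s[states]
    if config.dwell_mode != "explicit":
        raise ValueError("dwell_mode must be 'markov' or 'explicit'")
    # explicit-duration: lognormal dwells, then jump by renormalised off-diag row
    out = []
    cur = int(rng.choice(k, p=pi))
    while len(out) < n_windows:
        stay = sub[cur, cur]
        mean_dwell = 1.0 / max(1.0 - stay, 1e-6)
        dwell = max(1, int(round(rng.lognormal(np.log(mean_dwell), config.dwell_lognorm_sigma))))
        out.extend([cur] * dwell)
        off = sub[cur].copy()
        off[cur] = 0.0
        tot = off.sum()
        if tot <= 0:
            break
        cur = int(rng.choice(k, p=off / tot))
    return s[np.asarray(out[:n_windows], dtype=np.int64)]


# --------------------------------------------------------------------------
# feature-level generation


def simulate_features(
    states: np.ndarray, emission: EmissionParams, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Draw window features directly from the emission model given a state path."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = np.asarray(states, dtype=np.int64)
    vp = rng.normal(emission.varpitch_mean[states], emission.varpitch_sd[states])
    od = rng.normal(emission.odba_mean[states], emission.odba_sd[states])
    im = (rng.random(len(states)) < emission.immersion_prob[states]).astype(int)
    return pd.DataFrame(
        {"var_pitch_log10": vp, "mean_odba_log10": od, "immersed": im}
    )


def simulate_feature_study(
    config: SimConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature-level synthetic study.

    Returns ``(windows, truth)``: a model-ready window-feature frame and a
    truth frame with 1-based true state labels aligned row-for-row.
    """
    config = config or default_config()
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    streams = master.spawn(len(config.individuals))
    win_rows, truth_rows = [], []
    step = pd.Timedelta(seconds=config.window_s)
    for ind, ss in zip(config.individuals, streams):
        rng = np.random.default_rng(ss)
        states = simulate_states(config, ind.n_windows, ind.gravid, rng)
        feats = simulate_features(states, config.emission, rng)
        feats.insert(0, "individual_id", ind.individual_id)
        feats.insert(1, "burst_id", f"{ind.individual_id}_b0")
        feats.insert(2, "sex", ind.sex)
        feats.insert(3, "gravid", ind.gravid)
        feats.insert(4, "window_index", np.arange(ind.n_windows))
        feats.insert(5, "window_start", config.start_time + step * np.arange(ind.n_windows))
        win_rows.append(feats)
        truth_rows.append(
            pd.DataFrame(
                {
                    "individual_id": ind.individual_id,
                    "burst_id": f"{ind.individual_id}_b0",
                    "window_index": np.arange(ind.n_windows),
                    "true_state": states + 1,
                }
            )
        )
    return pd.concat(win_rows, ignore_index=True), pd.concat(truth_rows, ignore_index=True)


# --------------------------------------------------------------------------
# signal-level generation


def _quantize(x: np.ndarray, range_g: float, bits: int | None) -> np.ndarray:
    x = np.clip(x, -range_g, range_g)
    if bits is None:
        return x
    step = 2.0 * range_g / (2**bits)
    return np.clip(np.round(x / step) * step, -range_g, range_g)


def simulate_sensors(
    states: np.ndarray,
    config: SimConfig,
    seed: int | np.random.Generator,
    *,
    individual_id: str = "synthetic",
    sex: str = "female",
    gravid: bool = True,
    start_time: pd.Timestamp | None = None,
    burst_id: str | None = None,
) -> tuple[RawBurst, pd.DataFrame]:
    """Raw 10 Hz acceleration + 1 Hz immersion voltages for a state path.

    Each 30-s state block emits ``window_s * accel_hz`` accelerometer
    samples — a gravity vector rotated to the state's (jittered) mean pitch,
    plus the state's oscillation and white noise, clipped to the sensor
    range and quantised to the device's bit depth — and ``window_s *
    immersion_hz`` voltage samples from the state's wet/dry band. Returns
    the burst and its per-window truth table.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = np.asarray(states, dtype=np.int64)
    n_acc = int(round(config.window_s * config.accel_hz))
    n_imm = int(round(config.window_s * config.immersion_hz))
    n = len(states)
    ax = np.empty(n * n_acc)
    ay = np.empty(n * n_acc)
    az = np.empty(n * n_acc)
    volts = np.empty(n * n_imm)
    t_rel = np.arange(n_acc) / config.accel_hz
    ramp = t_rel / config.window_s
    for w, st in enumerate(states):
        sig = config.signals[STATE_NAMES[st]]
        # body orientation drifts within the block: linear pitch ramp
        # between two draws around the state's mean posture
        th0, th1 = np.radians(
            rng.normal(sig.pitch_mean_deg, sig.pitch_jitter_sd_deg, size=2)
        )
        theta = th0 + (th1 - th0) * ramp
        gx, gy, gz = np.sin(theta), 0.0, np.cos(theta)
        t_abs = t_rel + w * config.window_s
        if sig.dig:
            # rhythmic digging: sawtooth bursts separated by pauses
            cycle = config.dig_burst_s + config.dig_pause_s
            envelope = (np.mod(t_abs, cycle) < config.dig_burst_s).astype(float)
            saw = 2.0 * np.mod(t_abs * sig.osc_freq_hz, 1.0) - 1.0
            ox = sig.osc_amp_g[0] * saw * envelope
            oy = sig.osc_amp_g[1] * saw * envelope
            oz = np.zeros(n_acc)
        else:
            ph = rng.uniform(0, 2 * np.pi, size=3)
            ox = sig.osc_amp_g[0] * np.sin(2 * np.pi * sig.osc_freq_hz * t_abs + ph[0])
            oy = sig.osc_amp_g[1] * np.sin(2 * np.pi * sig.osc_freq_hz * t_abs + ph[1])
            oz = sig.osc_amp_g[2] * np.sin(2 * np.pi * sig.osc_freq_hz * t_abs + ph[2])
        noise = rng.normal(0.0, sig.noise_sd_g, size=(3, n_acc))
        sl = slice(w * n_acc, (w + 1) * n_acc)
        ax[sl] = gx + ox + noise[0]
        ay[sl] = gy + oy + noise[1]
        az[sl] = gz + oz + noise[2]
        vmean = config.voltage_wet_mean if sig.wet else config.voltage_dry_mean
        volts[w * n_imm : (w + 1) * n_imm] = rng.normal(vmean, config.voltage_sd, size=n_imm)
    burst = RawBurst(
        individual_id=individual_id,
        sex=sex,
        gravid=gravid,
        start_time=start_time if start_time is not None else config.start_time,
        ax=_quantize(ax, config.range_g, config.quantize_bits),
        ay=_quantize(ay, config.range_g, config.quantize_bits),
        az=_quantize(az, config.range_g, config.quantize_bits),
        analog_immersion=np.round(volts, 3),
        accel_hz=config.accel_hz,
        immersion_hz=config.immersion_hz,
        burst_id=burst_id or f"{individual_id}_b0",
        range_g=config.range_g,
    )
    truth = pd.DataFrame(
        {
            "individual_id": individual_id,
            "burst_id": burst.burst_id,
            "window_index": np.arange(n),
            "true_state": states + 1,
        }
    )
    return burst, truth


def simulate_deployment(
    config: SimConfig, ind: IndividualConfig, seed
) -> tuple[list[RawBurst], pd.DataFrame]:
    """All bursts + truth for one individual, honouring its dropout gap."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = simulate_states(config, ind.n_windows, ind.gravid, rng)
    cut = ind.dropout_after_windows
    pieces = [(0, ind.n_windows)] if not cut else [(0, cut), (cut, ind.n_windows)]
    bursts, truths = [], []
    t0 = config.start_time
    for b, (a, z) in enumerate(pieces):
        burst, truth = simulate_sensors(
            states[a:z],
            config,
            rng,
            individual_id=ind.individual_id,
            sex=ind.sex,
            gravid=ind.gravid,
            start_time=t0,
            burst_id=f"{ind.individual_id}_b{b}",
        )
        bursts.append(burst)
        truths.append(truth)
        t0 = t0 + pd.Timedelta(seconds=(z - a) * config.window_s + ind.dropout_gap_s)
    return bursts, pd.concat(truths, ignore_index=True)


def make_study(
    config: SimConfig | None = None, out_dir=None, seed: int | None = None
) -> dict:
    """Write a full signal-level study to disk (or return it in memory).

    Produces one CSV per individual in the reader's schema, a ground-truth
    window-label table, and the true parameter file. Returns a dict with
    the bursts, truth frame, per-individual metadata and written paths.
    """
    config = config or raw_study_config()
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    streams = master.spawn(len(config.individuals))
    all_bursts: dict[str, list[RawBurst]] = {}
    truths = []
    meta = []
    for ind, ss in zip(config.individuals, streams):
        bursts, truth = simulate_deployment(config, ind, np.random.default_rng(ss))
        all_bursts[ind.individual_id] = bursts
        truths.append(truth)
        meta.append(
            {"individual_id": ind.individual_id, "sex": ind.sex, "gravid": ind.gravid}
        )
    truth = pd.concat(truths, ignore_index=True)
    out = {"bursts": all_bursts, "truth": truth, "individuals": meta, "paths": {}}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        schema = default_schema()
        for ind in config.individuals:
            p = out_dir / f"{ind.individual_id}.csv"
            write_axy_csv(all_bursts[ind.individual_id], p, schema)
            out["paths"][ind.individual_id] = p
        truth.to_csv(out_dir / "truth.csv", index=False)
        params = {
            "tpm": config.tpm.tolist(),
            "emission": {
                "varpitch_mean": config.emission.varpitch_mean.tolist(),
                "varpitch_sd": config.emission.varpitch_sd.tolist(),
                "odba_mean": config.emission.odba_mean.tolist(),
                "odba_sd": config.emission.odba_sd.tolist(),
                "immersion_prob": config.emission.immersion_prob.tolist(),
            },
            "individuals": meta,
        }
        with open(out_dir / "true_params.json", "w") as fh:
            json.dump(params, fh, indent=1)
        out["paths"]["truth"] = out_dir / "truth.csv"
        out["paths"]["true_params"] = out_dir / "true_params.json"
    return out
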