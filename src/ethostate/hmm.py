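"""Constrained hidden Markov model for behavioural-state classification.

The model works on 30-s window features: log10 variance-in-pitch and log10
mean ODBA each get a state-dependent Normal distribution, binary immersion a
state-dependent Bernoulli, with the three channels conditionally independent
given the state. The transition matrix carries structural zeros for
ecologically impossible switches, and the state space is masked per track:
only gravid females can occupy Nesting, so their tracks are fitted with the
full 5-state chain while everyone else's use the 4-state sub-chain with
shared emission and transition parameters.

Estimation maximises the exact (scaled) forward likelihood directly with a
quasi-Newton optimizer on transformed working parameters — log standard
deviations, logit immersion probabilities (clamped), multinomial-logit
transition rows with the diagonal as reference and forbidden cells simply
absent, and one free simplex of initial probabilities per individual.

Usage follows the Model / Results convention::

    model = BehaviourHMM.from_dataframe(windows)
    res = model.fit()
    print(res.summary())
    decoded = res.decode()
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from ._kernels import forward_backward_kernel, forward_loglik_kernel, viterbi_kernel
from .states import (
    FORBIDDEN_TRANSITIONS,
    N_STATES,
    STATE_NAMES,
    StateLabel,
)

__all__ = [
    "EmissionParams",
    "TransitionStructure",
    "FittedParams",
    "BehaviourHMM",
    "HMMResults",
    "make_default_spec",
    "emission_loglik",
    "forward_loglik",
    "fit_hmm",
    "viterbi",
    "stationary_distribution",
]

PROB_CLAMP = 1e-12  # Bernoulli probabilities live in [clamp, 1 - clamp]

FEATURE_COLUMNS = ("var_pitch_log10", "mean_odba_log10", "immersed")


# --------------------------------------------------------------------------
# parameter containers


@dataclass
class EmissionParams:
    """State-dependent emission parameters (arrays of length n_states).

    Continuous channels are on the log10 scale of the window features;
    ``immersion_prob`` is the per-state probability that a window is scored
    as immersed.
    """

    varpitch_mean: np.ndarray
    varpitch_sd: np.ndarray
    odba_mean: np.ndarray
    odba_sd: np.ndarray
    immersion_prob: np.ndarray

    def __post_init__(self) -> None:
        for name in ("varpitch_mean", "varpitch_sd", "odba_mean", "odba_sd", "immersion_prob"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.varpitch_mean)
        if any(
            len(getattr(self, name)) != n
            for name in ("varpitch_sd", "odba_mean", "odba_sd", "immersion_prob")
        ):
            raise ValueError("emission parameter arrays must share one length")
        if np.any(self.varpitch_sd <= 0) or np.any(self.odba_sd <= 0):
            raise ValueError("emission standard deviations must be positive")
        self.immersion_prob = np.clip(self.immersion_prob, PROB_CLAMP, 1.0 - PROB_CLAMP)

    @property
    def n_states(self) -> int:
        return len(self.varpitch_mean)

    def to_frame(self, state_names: tuple[str, ...] | None = None) -> pd.DataFrame:
        names = state_names or _state_names(self.n_states)
        return pd.DataFrame(
            {
                "varpitch_mean": self.varpitch_mean,
                "varpitch_sd": self.varpitch_sd,
                "odba_mean": self.odba_mean,
                "odba_sd": self.odba_sd,
                "immersion_prob": self.immersion_prob,
            },
            index=list(names),
        )


@dataclass
class TransitionStructure:
    """Transition topology: state count, structural zeros, gravidity mask.

    ``forbidden`` holds 0-based ordered (from, to) index pairs whose
    probability is exactly zero (no parameter exists for them).
    ``masked_state`` is the state removed for non-gravid individuals.
    """

    n_states: int = N_STATES
    forbidden: frozenset = field(default_factory=lambda: FORBIDDEN_TRANSITIONS)
    masked_state: int | None = None

    def __post_init__(self) -> None:
        pairs = set()
        for a, b in self.forbidden:
            i = int(a) - 1 if isinstance(a, StateLabel) else int(a)
            j = int(b) - 1 if isinstance(b, StateLabel) else int(b)
            if not (0 <= i < self.n_states and 0 <= j < self.n_states):
                raise ValueError(f"forbidden pair ({a}, {b}) outside state space")
            if i == j:
                raise ValueError("self-transitions cannot be forbidden")
            pairs.add((i, j))
        self.forbidden = frozenset(pairs)
        if self.masked_state is None and self.n_states == N_STATES:
            self.masked_state = int(StateLabel.Nesting) - 1
        if self.masked_state is not None and not 0 <= self.masked_state < self.n_states:
            raise ValueError("masked_state outside state space")

    def mask(self) -> np.ndarray:
        """Boolean matrix, True where transitions are structurally zero."""
        m = np.zeros((self.n_states, self.n_states), dtype=bool)
        for i, j in self.forbidden:
            m[i, j] = True
        return m

    def free_pairs(self) -> list[tuple[int, int]]:
        """Off-diagonal, non-forbidden (row, col) pairs, row-major order."""
        m = self.mask()
        return [
            (i, j)
            for i in range(self.n_states)
            for j in range(self.n_states)
            if i != j and not m[i, j]
        ]

    def allowed_states(self, gravid: bool) -> np.ndarray:
        if gravid or self.masked_state is None:
            return np.arange(self.n_states)
        return np.array([k for k in range(self.n_states) if k != self.masked_state])


def _state_names(n: int) -> tuple[str, ...]:
    if n == N_STATES:
        return STATE_NAMES
    return tuple(f"state_{k + 1}" for k in range(n))


def make_default_spec() -> tuple[EmissionParams, TransitionStructure]:
    """Default 5-state specification: starting values and transition topology.

    Emission starting values (log10 units for the continuous channels):

    ================  ========  ========  ========  ========  =======
    statistic         ActiveW   ActiveL   InactW    InactL    Nesting
    ================  ========  ========  ========  ========  =======
    varpitch mean       -0.5      -0.5      -6        -6        0.2
    varpitch sd          3         2         3         2        1
    odba mean           -1        -0.5      -2        -2       -0.5
    odba sd              0.8       1         0.5       0.5      0.2
    P(immersed)        1-1e-12   1e-12    1-1e-12    1e-12     1e-12
    ================  ========  ========  ========  ========  =======
    """
    emission = EmissionParams(
        varpitch_mean=np.array([-0.5, -0.5, -6.0, -6.0, 0.2]),
        varpitch_sd=np.array([3.0, 2.0, 3.0, 2.0, 1.0]),
        odba_mean=np.array([-1.0, -0.5, -2.0, -2.0, -0.5]),
        odba_sd=np.array([0.8, 1.0, 0.5, 0.5, 0.2]),
        immersion_prob=np.array(
            [1.0 - PROB_CLAMP, PROB_CLAMP, 1.0 - PROB_CLAMP, PROB_CLAMP, PROB_CLAMP]
        ),
    )
    structure = TransitionStructure()
    return emission, structure


@dataclass
class FittedParams:
    """A fully realised parameter set, sufficient to decode new tracks."""

    emission: EmissionParams
    tpm: np.ndarray  # (K, K) row-stochastic, zeros at forbidden cells
    structure: TransitionStructure
    initials: dict[str, np.ndarray] = field(default_factory=dict)  # over full K

    def sub_tpm(self, gravid: bool) -> tuple[np.ndarray, np.ndarray]:
        """(allowed index array, renormalised sub-matrix) for one track."""
        s = self.structure.allowed_states(gravid)
        sub = self.tpm[np.ix_(s, s)]
        sub = sub / sub.sum(axis=1, keepdims=True)
        return s, sub

    def initial_for(self, individual_id: str, gravid: bool) -> np.ndarray:
        """Initial distribution over the allowed states of this track."""
        s, sub = self.sub_tpm(gravid)
        if individual_id in self.initials:
            delta = np.asarray(self.initials[individual_id], dtype=float)[s]
            tot = delta.sum()
            if tot > 0:
                return delta / tot
        return stationary_distribution(sub)

    def to_dict(self) -> dict:
        return {
            "n_states": self.structure.n_states,
            "state_names": list(_state_names(self.structure.n_states)),
            "emission": {
                "varpitch_mean": self.emission.varpitch_mean.tolist(),
                "varpitch_sd": self.emission.varpitch_sd.tolist(),
                "odba_mean": self.emission.odba_mean.tolist(),
                "odba_sd": self.emission.odba_sd.tolist(),
                "immersion_prob": self.emission.immersion_prob.tolist(),
            },
            "tpm": self.tpm.tolist(),
            "forbidden": sorted(self.structure.forbidden),
            "masked_state": self.structure.masked_state,
            "initials": {k: v.tolist() for k, v in self.initials.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedParams":
        emission = EmissionParams(**d["emission"])
        structure = TransitionStructure(
            n_states=d["n_states"],
            forbidden=frozenset(tuple(p) for p in d["forbidden"]),
            masked_state=d.get("masked_state"),
        )
        return cls(
            emission=emission,
            tpm=np.asarray(d["tpm"], dtype=float),
            structure=structure,
            initials={k: np.asarray(v, dtype=float) for k, v in d.get("initials", {}).items()},
        )

    def save(self, path) -> None:
        path = str(path)
        d = self.to_dict()
        if path.endswith((".yml", ".yaml")):
            import yaml

            with open(path, "w") as fh:
                yaml.safe_dump(d, fh)
        else:
            with open(path, "w") as fh:
                json.dump(d, fh, indent=1)

    @classmethod
    def load(cls, path) -> "FittedParams":
        path = str(path)
        if path.endswith((".yml", ".yaml")):
            import yaml

            with open(path) as fh:
                return cls.from_dict(yaml.safe_load(fh))
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# --------------------------------------------------------------------------
# emission densities


_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _normal_logpdf(x: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    z = (x[:, None] - mean[None, :]) / sd[None, :]
    return -0.5 * z * z - np.log(sd)[None, :] - _LOG_SQRT_2PI


def emission_logprob_matrix(
    varpitch: np.ndarray, odba: np.ndarray, immersed: np.ndarray, params: EmissionParams
) -> np.ndarray:
    """(T, K) matrix of per-window, per-state emission log-densities."""
    p = np.clip(params.immersion_prob, PROB_CLAMP, 1.0 - PROB_CLAMP)
    out = _normal_logpdf(np.asarray(varpitch, float), params.varpitch_mean, params.varpitch_sd)
    out += _normal_logpdf(np.asarray(odba, float), params.odba_mean, params.odba_sd)
    imm = np.asarray(immersed, float)[:, None]
    out += imm * np.log(p)[None, :] + (1.0 - imm) * np.log1p(-p)[None, :]
    return out


def emission_loglik(features, params: EmissionParams, state) -> np.ndarray | float:
    """Emission log-density of one or more windows under one state.

    ``features`` may be a mapping / Series with the three feature fields or a
    DataFrame; ``state`` is a :class:`StateLabel` or 0-based index. Returns a
    scalar for a single window, an array otherwise.
    """
    k = int(state) - 1 if isinstance(state, StateLabel) else int(state)
    if isinstance(features, pd.DataFrame):
        vp = features["var_pitch_log10"].to_numpy(float)
        od = features["mean_odba_log10"].to_numpy(float)
        im = features["immersed"].to_numpy(float)
        scalar = False
    else:
        vp = np.atleast_1d(np.asarray(features["var_pitch_log10"], float))
        od = np.atleast_1d(np.asarray(features["mean_odba_log10"], float))
        im = np.atleast_1d(np.asarray(features["immersed"], float))
        scalar = vp.size == 1
    if params.varpitch_sd[k] <= 0 or params.odba_sd[k] <= 0:
        raise ValueError("emission sd must be positive")
    col = emission_logprob_matrix(vp, od, im, params)[:, k]
    return float(col[0]) if scalar else col


# --------------------------------------------------------------------------
# stationary distribution


def stationary_distribution(tpm: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with pi P = pi, sum(pi) = 1.

    For a reducible chain (some states transient) the linear solve puts
    (numerically) zero mass on the transient states; a warning is emitted and
    the clipped solution renormalised.
    """
    P = np.asarray(tpm, dtype=float)
    k = P.shape[0]
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition matrix rows must sum to 1")
    A = np.vstack([P.T - np.eye(k), np.ones((1, k))])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.any(pi < -1e-9):
        warnings.warn("chain appears reducible; clipping negative stationary mass")
    pi = np.clip(pi, 0.0, None)
    tot = pi.sum()
    if tot <= 0:
        raise ValueError("no stationary distribution found")
    pi = pi / tot
    if np.any(pi < 1e-15) and np.any(np.diag(P) < 1.0):
        transient = np.flatnonzero(pi < 1e-15)
        if transient.size:
            warnings.warn(
                f"states {transient.tolist()} are transient; stationary mass is zero there"
            )
    return pi


# --------------------------------------------------------------------------
# tracks


@dataclass
class _Track:
    burst_id: str
    individual_id: str
    gravid: bool
    varpitch: np.ndarray
    odba: np.ndarray
    immersed: np.ndarray
    index: pd.Index  # original row labels, for decode output

    def __len__(self) -> int:
        return len(self.varpitch)


def _build_tracks(windows: pd.DataFrame) -> list[_Track]:
    required = {"individual_id", "burst_id", "gravid", *FEATURE_COLUMNS}
    missing = required - set(windows.columns)
    if missing:
        raise ValueError(f"windows frame is missing columns: {sorted(missing)}")
    if "window_index" in windows.columns:
        windows = windows.sort_values(["individual_id", "burst_id", "window_index"], kind="stable")
    tracks = []
    for (ind, burst), grp in windows.groupby(["individual_id", "burst_id"], sort=True):
        if len(grp) == 0:
            raise ValueError(f"track {ind}/{burst} has zero windows")
        vals = grp[list(FEATURE_COLUMNS)].to_numpy(float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite feature in track {ind}/{burst}")
        tracks.append(
            _Track(
                burst_id=str(burst),
                individual_id=str(ind),
                gravid=bool(grp["gravid"].iloc[0]),
                varpitch=np.ascontiguousarray(vals[:, 0]),
                odba=np.ascontiguousarray(vals[:, 1]),
                immersed=np.ascontiguousarray(vals[:, 2]),
                index=grp.index,
            )
        )
    if not tracks:
        raise ValueError("no tracks in windows frame")
    return tracks


# --------------------------------------------------------------------------
# working-parameter packing


class _Packer:
    """Maps between the flat working vector and realised parameters.

    Layout: [vp_mean (K), log vp_sd (K), odba_mean (K), log odba_sd (K),
    immersion logits (K, if estimated), TPM free logits (diagonal reference,
    forbidden cells absent), then per-individual initial logits (first
    allowed state is the reference)].
    """

    def __init__(
        self,
        structure: TransitionStructure,
        individuals: list[tuple[str, bool]],
        estimate_immersion: bool,
        per_individual_initial: bool,
    ) -> None:
        self.structure = structure
        self.K = structure.n_states
        self.estimate_immersion = estimate_immersion
        self.per_individual_initial = per_individual_initial
        self.pairs = structure.free_pairs()
        self.individuals = individuals
        self.init_sizes = [
            len(structure.allowed_states(grav)) - 1 for _, grav in individuals
        ] if per_individual_initial else []
        self.n_params = (
            4 * self.K
            + (self.K if estimate_immersion else 0)
            + len(self.pairs)
            + sum(self.init_sizes)
        )

    def bounds(self) -> list[tuple[float, float]]:
        """Loose box bounds on the working scale.

        Means are effectively free; log-SDs stay in a sane numeric range;
        probability logits are capped where the clamp saturates anyway, so
        boundary-seeking coordinates go inactive instead of drifting.
        """
        K = self.K
        b: list[tuple[float, float]] = []
        b += [(-50.0, 50.0)] * K  # varpitch means
        b += [(-10.0, 5.0)] * K  # log varpitch sd
        b += [(-50.0, 50.0)] * K  # odba means
        b += [(-10.0, 5.0)] * K  # log odba sd
        if self.estimate_immersion:
            b += [(-30.0, 30.0)] * K
        b += [(-30.0, 30.0)] * len(self.pairs)
        b += [(-30.0, 30.0)] * sum(self.init_sizes)
        return b

    def pack_start(self, emission: EmissionParams) -> np.ndarray:
        from scipy.special import logit

        K = self.K
        x = np.zeros(self.n_params)
        x[0:K] = emission.varpitch_mean
        x[K : 2 * K] = np.log(emission.varpitch_sd)
        x[2 * K : 3 * K] = emission.odba_mean
        x[3 * K : 4 * K] = np.log(emission.odba_sd)
        if self.estimate_immersion:
            p = np.clip(emission.immersion_prob, PROB_CLAMP, 1 - PROB_CLAMP)
            x[4 * K : 5 * K] = logit(p)
        # TPM logits and initial logits start at 0: uniform over allowed cells
        return x

    def unpack(
        self, x: np.ndarray, fixed_immersion: np.ndarray | None = None
    ) -> FittedParams:
        K = self.K
        off = 4 * K
        logsd_vp = np.clip(x[K : 2 * K], -20.0, 20.0)
        logsd_od = np.clip(x[3 * K : 4 * K], -20.0, 20.0)
        if self.estimate_immersion:
            p = np.clip(expit(x[off : off + K]), PROB_CLAMP, 1 - PROB_CLAMP)
            off += K
        else:
            p = fixed_immersion
        emission = EmissionParams(
            varpitch_mean=x[0:K].copy(),
            varpitch_sd=np.exp(logsd_vp),
            odba_mean=x[2 * K : 3 * K].copy(),
            odba_sd=np.exp(logsd_od),
            immersion_prob=p,
        )
        eta = np.full((K, K), -np.inf)
        np.fill_diagonal(eta, 0.0)
        for (i, j), v in zip(self.pairs, x[off : off + len(self.pairs)]):
            eta[i, j] = v
        off += len(self.pairs)
        m = eta.max(axis=1, keepdims=True)
        w = np.exp(eta - m)
        tpm = w / w.sum(axis=1, keepdims=True)
        initials: dict[str, np.ndarray] = {}
        if self.per_individual_initial:
            for (ind, grav), size in zip(self.individuals, self.init_sizes):
                s = self.structure.allowed_states(grav)
                logits = np.concatenate([[0.0], x[off : off + size]])
                off += size
                e = np.exp(logits - logits.max())
                delta_s = e / e.sum()
                full = np.zeros(K)
                full[s] = delta_s
                initials[ind] = full
        return FittedParams(
            emission=emission, tpm=tpm, structure=self.structure, initials=initials
        )


# --------------------------------------------------------------------------
# likelihood


def _track_loglik(track: _Track, params: FittedParams) -> float:
    log_b_full = emission_logprob_matrix(
        track.varpitch, track.odba, track.immersed, params.emission
    )
    s, sub = params.sub_tpm(track.gravid)
    delta = params.initial_for(track.individual_id, track.gravid)
    log_b = np.ascontiguousarray(log_b_full[:, s])
    return forward_loglik_kernel(log_b, np.ascontiguousarray(sub), np.ascontiguousarray(delta))


def forward_loglik(windows: pd.DataFrame, params: FittedParams) -> float:
    """Exact log-likelihood (nats) of a window-feature frame, summed over tracks.

    Individuals without an estimated initial distribution fall back to the
    stationary distribution of their (masked) transition matrix.
    """
    tracks = _build_tracks(windows)
    return float(sum(_track_loglik(t, params) for t in tracks))


def viterbi(params: FittedParams, windows: pd.DataFrame) -> pd.DataFrame:
    """Jointly most probable state path per track (ties to lower state index).

    Returns a copy of ``windows`` with integer ``state`` (1-based, matching
    :class:`StateLabel` for the 5-state model) and ``state_name`` columns.
    """
    tracks = _build_tracks(windows)
    out = windows.copy()
    out["state"] = -1
    names = _state_names(params.structure.n_states)
    for tr in tracks:
        log_b_full = emission_logprob_matrix(tr.varpitch, tr.odba, tr.immersed, params.emission)
        s, sub = params.sub_tpm(tr.gravid)
        delta = params.initial_for(tr.individual_id, tr.gravid)
        log_tpm = np.full_like(sub, -np.inf)
        pos = sub > 0
        log_tpm[pos] = np.log(sub[pos])
        log_delta = np.full(len(s), -np.inf)
        dpos = delta > 0
        log_delta[dpos] = np.log(delta[dpos])
        path = viterbi_kernel(
            np.ascontiguousarray(log_b_full[:, s]),
            np.ascontiguousarray(log_tpm),
            np.ascontiguousarray(log_delta),
        )
        out.loc[tr.index, "state"] = s[path] + 1
    out["state_name"] = [names[k - 1] for k in out["state"]]
    return out


# --------------------------------------------------------------------------
# model / results


class BehaviourHMM:
    """Constrained mixed-emission HMM over 30-s window features.

    Parameters
    ----------
    windows : DataFrame
        One row per complete 30-s window with columns ``individual_id``,
        ``burst_id``, ``gravid``, ``var_pitch_log10``, ``mean_odba_log10``,
        ``immersed`` (and optionally ``window_index`` / ``window_start``).
    start_emission, structure : optional
        Starting values and transition topology; defaults come from
        :func:`make_default_spec`.
    estimate_immersion : bool
        If False the Bernoulli probabilities stay fixed at their starting
        values (they remain clamped to [1e-12, 1-1e-12] either way).
    initial_mode : {"per_individual", "stationary"}
        Free initial simplex per individual (shared across that individual's
        bursts) or the stationary distribution of the masked chain.
    """

    def __init__(
        self,
        windows: pd.DataFrame,
        start_emission: EmissionParams | None = None,
        structure: TransitionStructure | None = None,
        *,
        estimate_immersion: bool = True,
        initial_mode: str = "per_individual",
    ) -> None:
        if start_emission is None or structure is None:
            em, st = make_default_spec()
            start_emission = start_emission or em
            structure = structure or st
        if start_emission.n_states != structure.n_states:
            raise ValueError("emission and transition structure disagree on n_states")
        if initial_mode not in ("per_individual", "stationary"):
            raise ValueError("initial_mode must be 'per_individual' or 'stationary'")
        self.windows = windows
        self.start_emission = start_emission
        self.structure = structure
        self.estimate_immersion = estimate_immersion
        self.initial_mode = initial_mode
        self.tracks = _build_tracks(windows)
        seen: dict[str, bool] = {}
        for t in self.tracks:
            seen.setdefault(t.individual_id, t.gravid)
            if seen[t.individual_id] != t.gravid:
                raise ValueError(f"individual {t.individual_id} has inconsistent gravid flags")
        self.individuals = sorted(seen.items())
        self._packer = _Packer(
            structure,
            self.individuals,
            estimate_immersion,
            per_individual_initial=(initial_mode == "per_individual"),
        )

    @classmethod
    def from_dataframe(cls, windows: pd.DataFrame, **kwargs) -> "BehaviourHMM":
        return cls(windows, **kwargs)

    # -- likelihood machinery ---------------------------------------------

    def _params_at(self, x: np.ndarray) -> FittedParams:
        return self._packer.unpack(x, fixed_immersion=self.start_emission.immersion_prob)

    def loglike(self, x: np.ndarray) -> float:
        """Log-likelihood at a working-parameter vector."""
        params = self._params_at(x)
        return float(sum(_track_loglik(t, params) for t in self.tracks))

    def loglike_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """Log-likelihood and its analytic gradient on the working scale.

        The gradient follows Fisher's identity: the score equals the
        posterior-weighted complete-data score, so one forward-backward
        pass per track yields every derivative — Normal means/log-SDs and
        immersion logits from the state posteriors, transition logits from
        expected transition counts against the (masked) softmax rows, and
        initial logits from the first-window posteriors. Only valid with
        per-individual initial distributions.
        """
        if self.initial_mode != "per_individual":
            raise NotImplementedError("analytic gradient needs per-individual initials")
        params = self._params_at(x)
        em = params.emission
        K = self.structure.n_states
        g_vp_mu = np.zeros(K)
        g_vp_lsd = np.zeros(K)
        g_od_mu = np.zeros(K)
        g_od_lsd = np.zeros(K)
        g_imm = np.zeros(K)
        g_eta = np.zeros((K, K))
        g_init = {ind: np.zeros(K) for ind, _ in self.individuals}
        ll_total = 0.0
        for tr in self.tracks:
            s, sub = params.sub_tpm(tr.gravid)
            delta = params.initial_for(tr.individual_id, tr.gravid)
            log_b = emission_logprob_matrix(tr.varpitch, tr.odba, tr.immersed, em)[:, s]
            ll, gamma, xi = forward_backward_kernel(
                np.ascontiguousarray(log_b),
                np.ascontiguousarray(sub),
                np.ascontiguousarray(delta),
            )
            if not np.isfinite(ll):
                return -np.inf, np.zeros(self._packer.n_params)
            ll_total += ll
            sd_vp = em.varpitch_sd[s]
            sd_od = em.odba_sd[s]
            z_vp = (tr.varpitch[:, None] - em.varpitch_mean[s][None, :]) / sd_vp[None, :]
            z_od = (tr.odba[:, None] - em.odba_mean[s][None, :]) / sd_od[None, :]
            g_vp_mu[s] += (gamma * z_vp / sd_vp[None, :]).sum(axis=0)
            g_vp_lsd[s] += (gamma * (z_vp**2 - 1.0)).sum(axis=0)
            g_od_mu[s] += (gamma * z_od / sd_od[None, :]).sum(axis=0)
            g_od_lsd[s] += (gamma * (z_od**2 - 1.0)).sum(axis=0)
            g_imm[s] += (
                gamma * (tr.immersed[:, None] - em.immersion_prob[s][None, :])
            ).sum(axis=0)
            g_eta[np.ix_(s, s)] += xi - sub * xi.sum(axis=1, keepdims=True)
            g_init[tr.individual_id][s] += gamma[0] - delta
        pieces = [g_vp_mu, g_vp_lsd, g_od_mu, g_od_lsd]
        if self.estimate_immersion:
            pieces.append(g_imm)
        pieces.append(np.array([g_eta[i, j] for i, j in self._packer.pairs]))
        for ind, grav in self.individuals:
            s = self.structure.allowed_states(grav)
            pieces.append(g_init[ind][s][1:])  # first allowed state is the reference
        return float(ll_total), np.concatenate(pieces)

    def _check_start(self, x0: np.ndarray) -> float:
        params = self._params_at(x0)
        total = 0.0
        for t in self.tracks:
            ll = _track_loglik(t, params)
            if not np.isfinite(ll):
                raise ValueError(
                    f"non-finite likelihood at start for track "
                    f"{t.individual_id}/{t.burst_id}"
                )
            total += ll
        return total

    def fit(
        self,
        *,
        tol: float = 1e-8,
        max_iter: int = 1000,
        n_restarts: int = 1,
        seed: int | None = None,
        verbose: bool = False,
        boundary_polish: bool = True,
    ) -> "HMMResults":
        """Maximise the forward likelihood with L-BFGS-B.

        ``n_restarts`` > 1 adds perturbed restarts of the working vector
        (Normal jitter, sd 0.5) and keeps the best optimum.

        Some working logits have their MLE at infinity (a transition that
        never occurs, a corner initial distribution, a saturated immersion
        probability); quasi-Newton steps drain those exponential tails
        slowly. ``boundary_polish`` snaps each logit coordinate to its box
        bound whenever that strictly improves the likelihood, re-optimises,
        and repeats once — a deterministic finishing step that leaves
        interior parameters to the optimizer.
        """
        x0 = self._packer.pack_start(self.start_emission)
        start_llf = self._check_start(x0)
        rng = np.random.default_rng(seed)
        best = None
        use_grad = self.initial_mode == "per_individual"

        def objective(x):
            if use_grad:
                ll, g = self.loglike_and_grad(x)
                return -ll, -g
            return -self.loglike(x)

        for r in range(max(1, n_restarts)):
            xr = x0 if r == 0 else x0 + rng.normal(0.0, 0.5, size=x0.shape)
            res = minimize(
                objective,
                xr,
                jac=use_grad if use_grad else None,
                method="L-BFGS-B",
                bounds=self._packer.bounds(),
                options={"maxiter": max_iter, "maxfun": 10 * max_iter * len(x0), "ftol": tol},
            )
            if verbose:
                print(f"restart {r}: llf={-res.fun:.4f} nit={res.nit} {res.message}")
            if best is None or -res.fun > -best.fun:
                best = res
        converged = bool(best.success)
        if not converged:
            warnings.warn(f"optimizer did not converge: {best.message}")
        llf = -best.fun
        x_hat = best.x
        if boundary_polish:
            x_hat, llf = self._polish_boundaries(x_hat, llf, objective, max_iter, tol)
        if llf < start_llf:  # L-BFGS-B never accepts an increase, but be explicit
            x_hat, llf, converged = x0, start_llf, False
        return HMMResults(
            model=self,
            params=self._params_at(x_hat),
            working_params=x_hat,
            llf=float(llf),
            start_llf=float(start_llf),
            converged=converged,
            niter=int(best.nit),
            message=str(best.message),
        )


    def _polish_boundaries(self, x, llf, objective, max_iter, tol):
        """Snap logit coordinates to their bounds where that improves the
        likelihood, then re-optimise; at most two cycles. Deterministic, and
        only ever accepts strict improvements."""
        K = self.structure.n_states
        bounds = self._packer.bounds()
        use_grad = self.initial_mode == "per_individual"

        def fval(z):
            out = objective(z)
            return out[0] if use_grad else out

        x = np.array(x, dtype=float)
        f = -llf
        for _ in range(2):
            improved = False
            for i in range(4 * K, len(x)):  # logit blocks only
                for target in bounds[i]:
                    if x[i] == target:
                        continue
                    xt = x.copy()
                    xt[i] = target
                    ft = fval(xt)
                    if ft < f - 1e-12:
                        x, f = xt, ft
                        improved = True
            if not improved:
                break
            res = _fit_polish_minimize(objective, x, use_grad, bounds, max_iter, tol)
            if res.fun < f:
                x, f = res.x, res.fun
        return x, -f


def _fit_polish_minimize(objective, x, use_grad, bounds, max_iter, tol):
    return minimize(
        objective,
        x,
        jac=use_grad if use_grad else None,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "maxfun": 10 * max_iter * len(x), "ftol": tol},
    )


class HMMResults:
    """Fitted-model results: estimates, diagnostics, decoding, summary."""

    def __init__(
        self,
        model: BehaviourHMM,
        params: FittedParams,
        working_params: np.ndarray,
        llf: float,
        start_llf: float,
        converged: bool,
        niter: int,
        message: str,
    ) -> None:
        self.model = model
        self.params = params
        self.working_params = working_params
        self.llf = llf
        self.start_llf = start_llf
        self.converged = converged
        self.niter = niter
        self.message = message

    @property
    def emission(self) -> EmissionParams:
        return self.params.emission

    @property
    def tpm(self) -> np.ndarray:
        return self.params.tpm

    @property
    def initial_distributions(self) -> dict[str, np.ndarray]:
        return self.params.initials

    @property
    def n_windows(self) -> int:
        return sum(len(t) for t in self.model.tracks)

    def decode(self, windows: pd.DataFrame | None = None) -> pd.DataFrame:
        """Viterbi decoding of the training windows (or new ones)."""
        return viterbi(self.params, self.model.windows if windows is None else windows)

    def summary(self) -> str:
        names = _state_names(self.params.structure.n_states)
        lines = []
        lines.append("Behavioural-state HMM results")
        lines.append("=" * 72)
        lines.append(
            f"windows: {self.n_windows}    tracks: {len(self.model.tracks)}    "
            f"individuals: {len(self.model.individuals)}"
        )
        lines.append(
            f"log-likelihood: {self.llf:.3f}   (at start: {self.start_llf:.3f})"
        )
        lines.append(
            f"converged: {self.converged}   iterations: {self.niter}   [{self.message}]"
        )
        lines.append("-" * 72)
        lines.append("state-dependent emissions (log10 feature scale)")
        lines.append(
            self.emission.to_frame(names).to_string(float_format=lambda v: f"{v:10.4f}")
        )
        lines.append("-" * 72)
        lines.append("transition probability matrix (full state space)")
        tpm = pd.DataFrame(self.tpm, index=list(names), columns=list(names))
        lines.append(tpm.to_string(float_format=lambda v: f"{v:8.4f}"))
        lines.append("-" * 72)
        lines.append("initial distributions per individual")
        for ind, grav in self.model.individuals:
            delta = self.params.initials.get(ind)
            if delta is None:
                _, sub = self.params.sub_tpm(grav)
                s = self.params.structure.allowed_states(grav)
                delta = np.zeros(len(names))
                delta[s] = stationary_distribution(sub)
            vec = "  ".join(f"{v:.4f}" for v in delta)
            lines.append(f"  {ind} (gravid={grav}): {vec}")
        return "\n".join(lines)

    def save(self, path) -> None:
        self.params.save(path)


def fit_hmm(
    windows: pd.DataFrame,
    start_emission: EmissionParams | None = None,
    structure: TransitionStructure | None = None,
    *,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_restarts: int = 1,
    seed: int | None = None,
    **model_kwargs,
) -> HMMResults:
    """One-call convenience wrapper: build a :class:`BehaviourHMM` and fit it."""
    model = BehaviourHMM(windows, start_emission, structure, **model_kwargs)
    return model.fit(tol=tol, max_iter=max_iter, n_restarts=n_restarts, seed=seed)
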