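"""Synthetic resting-state EEG cohorts with known ground truth.

Each subject is a 19-channel, 180 s, 256 Hz recording built from

* an aperiodic 1/f^|χ| background per channel (spectral-shaping of white
  Gaussian noise so the expected PSD is 10^offset · f^χ),
* band-limited oscillations (narrowband-filtered Gaussian processes) in
  the delta, theta and alpha ranges with group-specific RMS amplitudes,
* lagged phase coupling in the delta band over a group-specific backbone
  graph (a shared narrowband source injected into both channels of a
  pair, one copy phase-rotated by the pair's lag, with `strength` the
  proportion of band variance carried by the shared source), and
* instantaneous (zero-lag) linear channel mixing emulating scalp volume
  conduction.

The two groups mirror the directional contrasts of drug-resistant vs
drug-responsive epilepsy cohorts: the DRE-like group has higher delta
and lower alpha amplitude, a more negative aperiodic exponent and
offset, and a regular (1-D lattice) coupling backbone, whereas the
non-DRE-like group couples over an integrated hub topology. A matched
clinical covariate table (binary predictor rates echoing published
cohort contrasts, Gaussian continuous covariates) is generated alongside
full per-subject ground truth. Effect magnitudes are configuration
parameters; the defaults are calibrated study conditions of this
package, not claims about any clinical cohort.

Determinism: the cohort is a pure function of the master seed; subject
streams are derived counter-style as SeedSequence((master, subject)), so
enlarging the cohort never reshuffles earlier subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import firwin, fftconvolve, hilbert

from netsig.errors import ParameterError
from netsig.io import CHANNELS_1020, Recording


@dataclass
class ChannelSpec:
    """Generative spectral description of one channel."""

    exponent: float                       # aperiodic slope, <= 0
    offset: float                         # log10 µV²/Hz intercept
    oscillations: list[tuple[float, float, float]] = field(default_factory=list)
    # (center Hz, bandwidth Hz, RMS amplitude µV)

    def __post_init__(self):
        if self.exponent > 0:
            raise ParameterError("aperiodic exponent must be <= 0")
        for _, bw, amp in self.oscillations:
            if bw <= 0 or amp < 0:
                raise ParameterError("bandwidth > 0 and amplitude >= 0 required")


@dataclass
class CouplingSpec:
    """Lagged-coupling structure: simple undirected edges with per-pair
    phase lags (radians, in (0, π) for detectable wPLI) and a common
    coupling strength in [0, 1]."""

    band: tuple[float, float]
    edges: list[tuple[int, int]]
    lags: dict[tuple[int, int], float]
    strength: float = 0.85

    def __post_init__(self):
        seen = set()
        for i, j in self.edges:
            if i == j:
                raise ParameterError("coupling graph must be simple (no loops)")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ParameterError("coupling graph must be simple (no multi-edges)")
            seen.add(key)
        if not (0 <= self.strength <= 1):
            raise ParameterError("strength must lie in [0, 1]")


@dataclass
class GroupSpec:
    """Per-group generative parameters (means; subject values jittered)."""

    exponent: float
    offset: float
    amp_delta: float
    amp_alpha: float
    amp_theta: float
    topology: str                         # "lattice" or "integrated"


@dataclass
class CohortConfig:
    """Study conditions for a two-group synthetic cohort.

    Group A is the DRE-like group (outcome = 1), group B the
    non-DRE-like group (outcome = 0).
    """

    n_per_group: int = 60
    n_channels: int = 19
    fs: float = 256.0
    duration: float = 180.0
    seed: int = 0

    group_a: GroupSpec = field(default_factory=lambda: GroupSpec(
        exponent=-1.75, offset=0.50, amp_delta=3.4, amp_alpha=4.6,
        amp_theta=2.0, topology="lattice"))
    group_b: GroupSpec = field(default_factory=lambda: GroupSpec(
        exponent=-1.55, offset=0.70, amp_delta=2.9, amp_alpha=5.7,
        amp_theta=2.2, topology="integrated"))

    exponent_sd: float = 0.15
    offset_sd: float = 0.12
    amp_sd: float = 0.9
    #: per-edge probability that a backbone edge is rewired to a random
    #: non-backbone pair (per-subject topological heterogeneity)
    topology_rewire_p: float = 0.15
    coupling_band: tuple[float, float] = (2.0, 4.0)
    #: target coherent variance fraction per coupled pair; the per-group
    #: shared-source strength is derived from it so edge detectability
    #: (expected wPLI) is topology-independent
    coupling_fraction: float = 0.22
    lag_range: tuple[float, float] = (0.5, np.pi - 0.5)
    mixing_spread: float = 0.12

    #: Binary clinical predictor rates (group A, group B); the response
    #: and etiology contrasts echo published DRE cohort tables.
    clinical_rates: dict = field(default_factory=lambda: {
        "sex_female": (0.60, 0.45),
        "focal_epilepsy": (0.90, 0.917),
        "structural_etiology": (0.433, 0.167),
        "neuroimaging_abnormality": (0.70, 0.567),
        "tle": (0.783, 0.733),
        "response_first_asm": (0.183, 0.433),
    })
    #: Continuous covariates as ((mean_a, sd_a), (mean_b, sd_b)).
    clinical_continuous: dict = field(default_factory=lambda: {
        "age": ((46.7, 22.4), (50.6, 18.9)),
        "age_onset": ((33.3, 24.2), (38.8, 20.6)),
        "epilepsy_duration": ((13.5, 12.7), (12.5, 11.5)),
    })
    #: Median baseline 3-month seizure counts (log-normal draw).
    seizure_freq_median: tuple[float, float] = (3.0, 2.0)

    def __post_init__(self):
        if self.n_per_group < 1 or self.n_channels < 2:
            raise ParameterError("counts must be >= 1 (channels >= 2)")


# ---------------------------------------------------------------------------
# Signal primitives
# ---------------------------------------------------------------------------

def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_aperiodic_noise(exponent: float, offset: float, duration: float,
                        fs: float, seed=None) -> np.ndarray:
    """Gaussian noise whose expected one-sided PSD is 10^offset · f^exponent.

    Spectral shaping: white noise → rFFT → multiply amplitudes by
    sqrt(S(f) · fs/2) with S(f) = 10^offset f^exponent → inverse rFFT.
    The DC component is zeroed.
    """
    if exponent > 0:
        raise ParameterError("exponent must be <= 0")
    rng = _rng(seed)
    n = int(round(duration * fs))
    w = rng.standard_normal(n)
    W = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(f)
    # unit-variance white noise has one-sided density 2/fs, so gain
    # sqrt(S(f) * fs/2) yields expected density S(f)
    shape[1:] = np.sqrt((10.0 ** offset) * f[1:] ** exponent * fs / 2.0)
    return np.fft.irfft(W * shape, n=n)


def gen_oscillation(center: float, bandwidth: float, amplitude: float,
                    duration: float, fs: float, seed=None,
                    phase_offset: float = 0.0) -> np.ndarray:
    """Narrowband Gaussian oscillation at a target RMS amplitude.

    Band-pass-filtered white noise, rescaled to RMS ``amplitude``; a
    nonzero ``phase_offset`` rotates the analytic signal so two calls
    sharing a seed differ by a constant instantaneous phase lag.
    """
    if not (0 < center < fs / 2):
        raise ParameterError("center frequency must lie in (0, fs/2)")
    if amplitude == 0:
        return np.zeros(int(round(duration * fs)))
    rng = _rng(seed)
    n = int(round(duration * fs))
    lo = max(center - bandwidth / 2.0, 0.01)
    hi = min(center + bandwidth / 2.0, fs / 2.0 - 0.01)
    numtaps = int(np.ceil(6.0 * fs / bandwidth))
    numtaps += (numtaps + 1) % 2
    kernel = firwin(numtaps, [lo, hi], pass_zero=False, fs=fs, window="hamming")
    x = fftconvolve(rng.standard_normal(n), kernel, mode="same")
    if phase_offset != 0.0:
        x = np.real(hilbert(x) * np.exp(-1j * phase_offset))
    rms = np.sqrt(np.mean(x ** 2))
    return x * (amplitude / rms)


def mix_zero_lag(channels: np.ndarray, mixing: np.ndarray) -> np.ndarray:
    """Instantaneous linear mixture: out = mixing @ channels.

    Introduces zero-lag correlations only (the volume-conduction
    emulator); the matrix must be square and nonsingular.
    """
    mixing = np.asarray(mixing, dtype=float)
    if mixing.ndim != 2 or mixing.shape[0] != mixing.shape[1]:
        raise ParameterError("mixing matrix must be square")
    if mixing.shape[0] != channels.shape[0]:
        raise ParameterError("mixing matrix size must match channel count")
    if np.linalg.cond(mixing) > 1e10:
        raise ParameterError("mixing matrix is singular or near-singular")
    return mixing @ channels


# ---------------------------------------------------------------------------
# Coupling backbones
# ---------------------------------------------------------------------------

def coupling_backbone(topology: str, n_channels: int, rng,
                      n_edges: int = 9) -> list[tuple[int, int]]:
    """Group-specific coupling backbone over a random channel subset.

    ``lattice``: a 1-D lattice segment (simple path over n_edges+1
    nodes) — regular, long paths, no triangles; the DRE-like condition.
    ``integrated``: a ten-node double star plus one closing triangle
    edge — short paths, high reach and (usually, after binarization)
    nonzero clustering; the non-DRE-like condition.
    """
    if topology == "lattice":
        nodes = rng.choice(n_channels, size=n_edges + 1, replace=False)
        return [(int(nodes[k]), int(nodes[k + 1])) for k in range(n_edges)]
    if topology == "integrated":
        # double star spanning ten nodes plus one closing triangle edge
        # (10 edges; 5% binarization keeps 9): short paths, high reach,
        # and — in most realizations — nonzero clustering
        n = [int(v) for v in rng.choice(n_channels, size=10, replace=False)]
        h1, h2 = n[0], n[1]
        return ([(h1, h2)]
                + [(h1, leaf) for leaf in n[2:6]]
                + [(h2, leaf) for leaf in n[6:10]]
                + [(n[2], n[3])])
    raise ParameterError(f"unknown coupling topology {topology!r}")


def make_coupling(topology: str, n_channels: int, band: tuple[float, float],
                  lag_range: tuple[float, float], rng,
                  strength: float | None = None,
                  fraction: float | None = 0.12,
                  rewire_p: float = 0.0) -> CouplingSpec:
    """Build a CouplingSpec for a group topology.

    Either pass ``strength`` (shared variance proportion per channel)
    directly, or a target per-pair coherent ``fraction`` from which the
    strength is derived given the backbone's degree-balanced source
    weights (so different topologies yield comparable edge wPLI).
    ``rewire_p`` replaces each backbone edge by a random non-backbone
    pair with that probability (subject-level topological noise).
    """
    edges = [(min(i, j), max(i, j))
             for i, j in coupling_backbone(topology, n_channels, rng)]
    if rewire_p > 0:
        current = set(edges)
        for k, e in enumerate(edges):
            if rng.random() < rewire_p:
                for _ in range(100):
                    i, j = rng.choice(n_channels, size=2, replace=False)
                    cand = (min(int(i), int(j)), max(int(i), int(j)))
                    if cand not in current:
                        current.discard(e)
                        current.add(cand)
                        edges[k] = cand
                        break
    lags = {e: float(rng.uniform(*lag_range)) for e in edges}
    if strength is None:
        if fraction is None:
            raise ParameterError("pass strength or fraction")
        w = _edge_source_weights(edges, n_channels)
        amps = [w[i][(i, j)] * w[j][(i, j)] for i, j in edges]
        a_geo = float(np.exp(np.mean(np.log(amps))))
        strength = float(np.clip(fraction / a_geo ** 2, 0.05, 0.95))
    return CouplingSpec(band=band, edges=edges, lags=lags, strength=strength)


def _edge_source_weights(edges, n_channels: int, iters: int = 200) -> dict:
    """Per-channel weights for incident shared sources, balanced so every
    edge has (approximately) equal coherent amplitude w_ie · w_je.

    A channel of degree d splits unit variance across its d sources;
    the naive 1/sqrt(d) split makes edges between high-degree nodes much
    harder to detect than leaf edges. Multiplicative rebalancing toward
    the geometric-mean coherent amplitude evens out edge detectability.
    """
    w = {}
    for i, j in edges:
        for c in (i, j):
            w.setdefault(c, {})[(i, j)] = 1.0
    for c in w:  # start at the equal split
        d = len(w[c])
        for e in w[c]:
            w[c][e] = 1.0 / np.sqrt(d)
    for _ in range(iters):
        amps = {e: w[e[0]][e] * w[e[1]][e] for e in edges}
        target = float(np.exp(np.mean(np.log(list(amps.values())))))
        for i, j in edges:
            adj = (target / amps[(i, j)]) ** 0.25
            w[i][(i, j)] *= adj
            w[j][(i, j)] *= adj
        for c in w:  # renormalize channel variance
            norm = np.sqrt(sum(v ** 2 for v in w[c].values()))
            for e in w[c]:
                w[c][e] /= norm
    return w


def _coupled_band_signals(coupling: CouplingSpec, n_channels: int,
                          duration: float, fs: float, rng) -> np.ndarray:
    """Unit-RMS per-channel band signals realizing the coupling graph.

    Every coupled channel mixes its incident shared sources (one copy
    per edge, the second endpoint phase-rotated by the edge lag) with a
    private narrowband component so that `strength` is the shared
    fraction of band variance; uncoupled channels are purely private.
    Source weights are degree-balanced (see `_edge_source_weights`).
    """
    center = (coupling.band[0] + coupling.band[1]) / 2.0
    bw = coupling.band[1] - coupling.band[0]
    n = int(round(duration * fs))
    shared: dict[tuple[int, int], np.ndarray] = {}
    for e in coupling.edges:
        s = gen_oscillation(center, bw, 1.0, duration, fs, seed=rng)
        shared[e] = hilbert(s)                       # analytic, for rotation
    weights = _edge_source_weights(coupling.edges, n_channels)
    out = np.zeros((n_channels, n))
    s_w = np.sqrt(coupling.strength)
    p_w = np.sqrt(1.0 - coupling.strength)
    for c in range(n_channels):
        incident = [e for e in coupling.edges if c in e]
        if incident:
            acc = np.zeros(n)
            for e in incident:
                phase = coupling.lags[e] if c == e[1] else 0.0
                acc += weights[c][e] * np.real(shared[e] * np.exp(-1j * phase))
            sig = s_w * acc + p_w * gen_oscillation(center, bw, 1.0, duration,
                                                    fs, seed=rng)
        else:
            sig = gen_oscillation(center, bw, 1.0, duration, fs, seed=rng)
        out[c] = sig / np.sqrt(np.mean(sig ** 2))
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _subject_rng(master_seed: int, stream: int, group_idx: int,
                 k: int) -> np.random.Generator:
    """Counter-based sub-stream: (master, stream, group, subject-in-group),
    so enlarging the cohort never reshuffles earlier subjects."""
    return np.random.default_rng(
        np.random.SeedSequence((master_seed, stream, group_idx, k)))


def _gen_subject(cfg: CohortConfig, group: GroupSpec, group_idx: int, k: int,
                 index: int, label: str) -> tuple[Recording, dict]:
    rng = _subject_rng(cfg.seed, 1, group_idx, k)
    n_ch = cfg.n_channels
    n = int(round(cfg.duration * cfg.fs))
    labels = (CHANNELS_1020 if n_ch == len(CHANNELS_1020)
              else [f"ch{i}" for i in range(n_ch)])

    exponent = min(group.exponent + rng.normal(0, cfg.exponent_sd), -0.05)
    offset = group.offset + rng.normal(0, cfg.offset_sd)
    amp_delta = max(group.amp_delta + rng.normal(0, cfg.amp_sd), 0.3)
    amp_alpha = max(group.amp_alpha + rng.normal(0, cfg.amp_sd), 0.3)
    amp_theta = max(group.amp_theta + rng.normal(0, cfg.amp_sd / 2), 0.3)

    coupling = make_coupling(group.topology, n_ch, cfg.coupling_band,
                             cfg.lag_range, rng,
                             fraction=cfg.coupling_fraction,
                             rewire_p=cfg.topology_rewire_p)
    delta = _coupled_band_signals(coupling, n_ch, cfg.duration, cfg.fs, rng)

    data = np.zeros((n_ch, n))
    for c in range(n_ch):
        chi = min(exponent + rng.normal(0, 0.03), -0.01)
        data[c] = gen_aperiodic_noise(chi, offset + rng.normal(0, 0.02),
                                      cfg.duration, cfg.fs, seed=rng)
        data[c] += amp_delta * delta[c]
        data[c] += gen_oscillation(6.0, 2.0, amp_theta, cfg.duration, cfg.fs,
                                   seed=rng)
        data[c] += gen_oscillation(10.0, 3.0, amp_alpha, cfg.duration, cfg.fs,
                                   seed=rng)

    mixing = np.eye(n_ch) + cfg.mixing_spread * (
        rng.standard_normal((n_ch, n_ch)) / np.sqrt(n_ch))
    np.fill_diagonal(mixing, 1.0)
    data = mix_zero_lag(data, mixing)

    rec = Recording(data=data, fs=cfg.fs, labels=labels,
                    meta={"subject_id": f"S{index:03d}", "group": label,
                          "synthetic": True})
    truth = {
        "subject_id": f"S{index:03d}",
        "group": label,
        "exponent": exponent,
        "offset": offset,
        "amp_delta": amp_delta,
        "amp_alpha": amp_alpha,
        "amp_theta": amp_theta,
        "coupling_edges": coupling.edges,
        "coupling_lags": coupling.lags,
        "topology": group.topology,
    }
    return rec, truth


def _gen_clinical(cfg: CohortConfig, group_idx: int, k: int, index: int,
                  group_is_a: bool) -> dict:
    rng = _subject_rng(cfg.seed, 2, group_idx, k)
    g = 0 if group_is_a else 1
    row = {"subject_id": f"S{index:03d}", "outcome": int(group_is_a)}
    for name, rates in cfg.clinical_rates.items():
        row[name] = int(rng.random() < rates[g])
    row["sba_present"] = row["neuroimaging_abnormality"]
    for name, params in cfg.clinical_continuous.items():
        mean, sd = params[g]
        row[name] = float(np.clip(rng.normal(mean, sd), 0.5, 95.0))
    med = cfg.seizure_freq_median[g]
    row["baseline_seizure_freq"] = int(max(1, round(
        np.exp(rng.normal(np.log(med), 0.9)))))
    row["n_seizure_types"] = int(1 + rng.binomial(2, 0.25 if group_is_a else 0.15))
    return row


def gen_cohort(cfg: CohortConfig):
    """Generate a full two-group cohort.

    Returns
    -------
    recordings : list of Recording
        Group A (DRE-like) subjects first, then group B.
    clinical : pandas.DataFrame
        One row per subject with outcome and clinical predictors.
    ground_truth : pandas.DataFrame
        Realized per-subject generative parameters (coupling graph
        included as object columns).
    """
    recordings, truths, clin_rows = [], [], []
    for k in range(cfg.n_per_group):
        rec, truth = _gen_subject(cfg, cfg.group_a, 0, k, k, "A")
        recordings.append(rec)
        truths.append(truth)
        clin_rows.append(_gen_clinical(cfg, 0, k, k, True))
    for k in range(cfg.n_per_group):
        idx = cfg.n_per_group + k
        rec, truth = _gen_subject(cfg, cfg.group_b, 1, k, idx, "B")
        recordings.append(rec)
        truths.append(truth)
        clin_rows.append(_gen_clinical(cfg, 1, k, idx, False))
    clinical = pd.DataFrame(clin_rows)
    ground_truth = pd.DataFrame(truths)
    return recordings, clinical, ground_truth
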