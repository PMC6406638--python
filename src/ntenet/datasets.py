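"""Synthetic EEG cohorts with known directed coupling.

No public recordings accompany the novice/expert CAD study this package
analyses, so every downstream stage is exercised on simulated 14-channel
recordings whose ground-truth coupling is stored next to the data.

The generative model is a nonlinearly coupled AR(1) network: channel *i*
evolves as

    x_i[t] = a * x_i[t-1] + s(state) * sum_j g_ij * tanh(x_j[t-1])
             + A * sin(2*pi*10*t/fs + phi_i) + L * sin(2*pi*50*t/fs) + eps,

with eps ~ N(0, noise_sd^2). The tanh coupling gives the non-linear
cross-channel dependence that transfer entropy is designed to detect, the
10 Hz term mimics an alpha rhythm, and the 50 Hz term mimics mains
contamination (so the notch filter has something to do). The per-state
multiplier s encodes the study's behavioural ground truth: novices engage
progressively harder from rest through drawing to manipulation, while
experts plateau once the task starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import CHANNEL_INDEX, N_CHANNELS
from .recording import Annotation, MultichannelRecording

STATES = ("rest", "drawing", "manipulation")

#: AR memory of every channel. Short enough that a channel's next sample is
#: not already determined by its own past: with very long memory (a -> 1)
#: the integrated drive becomes self-predictable and the measurable
#: cross-channel transfer entropy stops growing with coupling strength.
ALPHA = 0.6

#: Relative tolerance under which an expert's drawing and manipulation
#: engagement count as "approximately the same".
EXPERT_FLAT_TOL = 0.05

# Observed task durations in the source cohort (seconds); rest is the
# scripted two-minute baseline.
DRAWING_RANGE = (38, 137)
MANIPULATION_RANGE = (72, 125)
REST_SECONDS = 120.0

# Per-state engagement multipliers. The novice profile rises monotonically
# across states; the expert profile rises into drawing and stays flat, at a
# higher task level than the novice's drawing (experts sustain practiced
# engagement from the start of the task; novices ramp up late).
NOVICE_SCALES = {"rest": 0.35, "drawing": 0.7, "manipulation": 1.3}
EXPERT_SCALES = {"rest": 0.35, "drawing": 1.0, "manipulation": 1.0}


@dataclass
class CouplingSpec:
    """Ground-truth directed coupling. ``matrix[i, j]`` drives j -> i."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (N_CHANNELS, N_CHANNELS):
            raise ValueError(
                f"coupling matrix must be {N_CHANNELS}x{N_CHANNELS}, "
                f"got {self.matrix.shape}"
            )
        if (self.matrix < 0).any():
            raise ValueError("coupling strengths must be nonnegative")
        if np.diagonal(self.matrix).any():
            raise ValueError("coupling diagonal must be exactly zero")

    @property
    def coupled_pairs(self) -> list[tuple[int, int]]:
        """(source, target) index pairs with nonzero coupling."""
        tgt, src = np.nonzero(self.matrix)
        return list(zip(src.tolist(), tgt.tolist()))


@dataclass
class SubjectProfile:
    """Everything that makes one simulated subject reproducible."""

    subject_id: str
    expertise: str
    state_durations: dict[str, float]
    coupling_scale: dict[str, float]
    noise_sd: float = 1.0
    line_noise_amplitude: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.expertise not in ("novice", "expert"):
            raise ValueError(f"unknown expertise {self.expertise!r}")
        for s in STATES:
            if s not in self.state_durations:
                raise ValueError(f"missing duration for state {s!r}")
            if self.state_durations[s] <= 0:
                raise ValueError(f"duration for {s!r} must be positive")
            if s not in self.coupling_scale:
                raise ValueError(f"missing coupling multiplier for {s!r}")
            if self.coupling_scale[s] < 0:
                raise ValueError("coupling multipliers must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        r, d, m = (self.coupling_scale[s] for s in STATES)
        if self.expertise == "novice":
            if not (r < d < m):
                raise ValueError(
                    "novice profile requires scale(rest) < scale(drawing) "
                    "< scale(manipulation)"
                )
        else:
            if not (r < d and abs(d - m) <= EXPERT_FLAT_TOL * d):
                raise ValueError(
                    "expert profile requires scale(rest) < scale(drawing) "
                    "and drawing ~= manipulation (within 5%)"
                )


def default_coupling() -> CouplingSpec:
    """The default ground-truth network used by :func:`make_cohort`.

    A sparse frontally weighted digraph: frontal sites drive central and
    parietal ones (with a few feedback and interhemispheric links), echoing
    the front-to-back information-flow pattern the analysis is meant to
    resolve. Strengths are modest so that the tanh drive never saturates
    the AR dynamics.
    """
    edges = {
        # frontal -> central/temporal
        ("F3", "FC5"): 0.45, ("F3", "T7"): 0.30, ("F4", "FC6"): 0.45,
        ("F4", "T8"): 0.30, ("F7", "FC5"): 0.30, ("F8", "FC6"): 0.30,
        # frontal -> parietal/occipital
        ("F3", "P7"): 0.25, ("F4", "P8"): 0.25, ("AF3", "O1"): 0.20,
        ("AF4", "O2"): 0.20,
        # central -> parietal
        ("FC5", "P7"): 0.35, ("FC6", "P8"): 0.35, ("T7", "O1"): 0.30,
        ("T8", "O2"): 0.30,
        # feedback parietal -> frontal
        ("P7", "F3"): 0.20, ("P8", "F4"): 0.20,
        # interhemispheric
        ("F3", "F4"): 0.25, ("F4", "F3"): 0.25, ("AF3", "AF4"): 0.20,
        ("O1", "O2"): 0.20,
    }
    g = np.zeros((N_CHANNELS, N_CHANNELS))
    for (src, tgt), w in edges.items():
        g[CHANNEL_INDEX[tgt], CHANNEL_INDEX[src]] = w
    return CouplingSpec(g)


def simulate_subject(
    profile: SubjectProfile,
    base_coupling: CouplingSpec | None = None,
    fs: float = 128.0,
    alpha_amplitude: float | None = None,
    burn_in_seconds: float = 2.0,
) -> MultichannelRecording:
    """Simulate one subject's recording across rest, drawing, manipulation.

    The three states are generated back-to-back with the network state
    carried across boundaries (only the engagement multiplier switches).
    The initial transient is discarded. Deterministic given the profile's
    seed.

    Parameters
    ----------
    alpha_amplitude : float, optional
        Amplitude A of the 10 Hz rhythm; defaults to ``0.5 * noise_sd``.
    """
    if fs < 64:
        raise ValueError("fs must be at least 64 Hz")
    g = (base_coupling or default_coupling()).matrix
    rng = np.random.default_rng(profile.seed)
    a_amp = 0.5 * profile.noise_sd if alpha_amplitude is None else alpha_amplitude
    phi = rng.uniform(0, 2 * np.pi, size=N_CHANNELS)

    n_burn = int(round(burn_in_seconds * fs))
    lengths = [int(round(profile.state_durations[s] * fs)) for s in STATES]
    n_total = n_burn + sum(lengths)

    # Per-sample engagement multiplier (burn-in runs at the rest level).
    scale = np.empty(n_total)
    scale[:n_burn] = profile.coupling_scale["rest"]
    pos = n_burn
    annotations = []
    for s, n in zip(STATES, lengths):
        scale[pos:pos + n] = profile.coupling_scale[s]
        annotations.append(Annotation(s, pos - n_burn, pos - n_burn + n))
        pos += n

    t = np.arange(n_total)
    alpha_wave = a_amp * np.sin(2 * np.pi * 10.0 * t[None, :] / fs
                                + phi[:, None])
    line = profile.line_noise_amplitude * np.sin(2 * np.pi * 50.0 * t / fs)
    noise = rng.normal(0.0, profile.noise_sd, size=(N_CHANNELS, n_total))
    drive = alpha_wave + line[None, :] + noise

    x = np.zeros((N_CHANNELS, n_total))
    prev = np.zeros(N_CHANNELS)
    for k in range(n_total):
        prev = ALPHA * prev + scale[k] * (g @ np.tanh(prev)) + drive[:, k]
        x[:, k] = prev

    return MultichannelRecording(x[:, n_burn:], fs, annotations)


def make_cohort(
    n_novice: int = 5,
    n_expert: int = 3,
    seed: int = 0,
    base_coupling: CouplingSpec | None = None,
    fs: float = 128.0,
    duration_scale: float = 1.0,
    noise_sd: float = 1.0,
    line_noise_amplitude: float = 0.5,
) -> list[tuple[MultichannelRecording, SubjectProfile, CouplingSpec]]:
    """Simulate a cohort (default 5 novices + 3 experts, as in the study).

    Per-subject seeds and durations derive reproducibly from ``seed``;
    drawing and manipulation durations are drawn uniformly within the
    ranges observed in the source cohort, rest is fixed at two minutes.
    Each subject's engagement multipliers get an overall +/-10% factor so
    subjects are not identical, which preserves the per-profile shape
    constraints (monotone for novices, flat task plateau for experts).

    ``duration_scale`` shrinks or stretches every state duration; useful
    for quick end-to-end runs.
    """
    if n_novice < 0 or n_expert < 0:
        raise ValueError("cohort counts must be nonnegative")
    coupling = base_coupling or default_coupling()
    master = np.random.default_rng(seed)
    out = []
    labels = ["novice"] * n_novice + ["expert"] * n_expert
    for i, expertise in enumerate(labels):
        sub_seed = int(master.integers(0, 2**31 - 1))
        sub_rng = np.random.default_rng(sub_seed)
        durations = {
            "rest": REST_SECONDS * duration_scale,
            "drawing": float(sub_rng.uniform(*DRAWING_RANGE)) * duration_scale,
            "manipulation": float(sub_rng.uniform(*MANIPULATION_RANGE))
            * duration_scale,
        }
        level = float(sub_rng.uniform(0.9, 1.1))
        base = NOVICE_SCALES if expertise == "novice" else EXPERT_SCALES
        scales = {s: level * v for s, v in base.items()}
        profile = SubjectProfile(
            subject_id=f"S{i + 1:02d}",
            expertise=expertise,
            state_durations=durations,
            coupling_scale=scales,
            noise_sd=noise_sd,
            line_noise_amplitude=line_noise_amplitude,
            seed=sub_seed,
        )
        rec = simulate_subject(profile, coupling, fs)
        out.append((rec, profile, coupling))
    return out
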