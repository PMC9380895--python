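"""Synthetic gait cohorts with trait-driven kinematics.

Each subject gets a latent Big Five vector drawn from a correlated
Gaussian (extraversion, agreeableness, conscientiousness and openness
mutually positive, all negative with neuroticism — the usual inter-scale
pattern), BFI-44-range subscale sums obtained by scaling the latent trait
and adding score noise, and a 75-frame walking sequence in which five
kinematic parameters are linear functions of the latent traits:

* arm-swing amplitude   <- extraversion
* torso-sway amplitude  <- agreeableness
* stride amplitude      <- conscientiousness
* gait period (cadence) <- neuroticism (higher N, slower cadence)
* head-bob amplitude    <- openness

Limbs oscillate sinusoidally about a fixed standing pose, left and right
in antiphase, with arms counter-phased to their same-side leg; additive
Gaussian pixel noise models pose-estimator jitter.  The walker is
body-centred (no net translation along the walkway): downstream features
are invariant to global position anyway, since MidHip becomes the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .modeling import TRAITS
from .schema import GaitSequence

#: Subscale sum ranges (items x 1 .. items x 5).
SCORE_RANGES: dict[str, tuple[int, int]] = {
    "extraversion": (8, 40),
    "agreeableness": (9, 45),
    "conscientiousness": (9, 45),
    "neuroticism": (8, 40),
    "openness": (10, 50),
}

#: Score = center + slope * latent + noise, rounded and clipped to range.
SCORE_CENTERS = {t: (lo + hi) / 2 for t, (lo, hi) in SCORE_RANGES.items()}
SCORE_SLOPES = {
    "extraversion": 4.5,
    "agreeableness": 5.0,
    "conscientiousness": 5.0,
    "neuroticism": 4.5,
    "openness": 5.5,
}

KINEMATIC_PARAMS = ("arm_swing", "torso_sway", "stride", "gait_period", "head_bob")

#: Rest pose, pixels, image-style axes (x right, y down), ~400 px tall
#: walker centred in a 1920x1080 frame.
DEFAULT_BASE_POSE: dict[int, tuple[float, float]] = {
    0: (960, 360),   # Nose
    1: (960, 400),   # Neck
    2: (930, 405), 3: (925, 470), 4: (920, 535),    # right arm
    5: (990, 405), 6: (995, 470), 7: (1000, 535),   # left arm
    8: (960, 540),   # MidHip
    9: (940, 545), 10: (935, 640), 11: (930, 735),  # right leg
    12: (980, 545), 13: (985, 640), 14: (990, 735),  # left leg
    15: (950, 350), 16: (970, 350), 17: (940, 355), 18: (980, 355),  # eyes/ears
    19: (995, 755), 20: (1005, 755), 21: (985, 750),   # left foot
    22: (925, 755), 23: (915, 755), 24: (935, 750),    # right foot
}


def _default_trait_corr() -> np.ndarray:
    corr = np.full((5, 5), 0.3)
    np.fill_diagonal(corr, 1.0)
    n_idx = TRAITS.index("neuroticism")
    corr[n_idx, :] = -0.4
    corr[:, n_idx] = -0.4
    corr[n_idx, n_idx] = 1.0
    return corr


def _default_effect_matrix() -> np.ndarray:
    # rows: traits (TRAITS order); columns: KINEMATIC_PARAMS
    eff = np.zeros((5, 5))
    eff[TRAITS.index("extraversion"), KINEMATIC_PARAMS.index("arm_swing")] = 8.0
    eff[TRAITS.index("agreeableness"), KINEMATIC_PARAMS.index("torso_sway")] = 3.0
    eff[TRAITS.index("conscientiousness"), KINEMATIC_PARAMS.index("stride")] = 10.0
    eff[TRAITS.index("neuroticism"), KINEMATIC_PARAMS.index("gait_period")] = 4.0
    eff[TRAITS.index("openness"), KINEMATIC_PARAMS.index("head_bob")] = 2.5
    return eff


@dataclass
class SyntheticConfig:
    """Cohort generation settings.

    ``effect_matrix`` (5 traits x 5 kinematic parameters) holds the linear
    coefficients, in pixels (or frames, for the gait period) per latent-SD;
    ``effect_scale`` rescales it wholesale — 0 gives a null cohort where
    kinematics carry no trait signal.
    """

    n_subjects: int = 150
    n_frames: int = 75
    gait_period: float = 25.0         # frames per stride cycle
    arm_swing: float = 25.0           # px
    torso_sway: float = 6.0           # px
    stride: float = 40.0              # px
    head_bob: float = 5.0             # px
    noise_sd: float = 1.0             # px of keypoint jitter
    score_noise_sd: float = 2.0       # score points
    effect_matrix: np.ndarray = field(default_factory=_default_effect_matrix)
    effect_scale: float = 1.0
    trait_corr: np.ndarray = field(default_factory=_default_trait_corr)
    seed: int = 0

    def __post_init__(self) -> None:
        self.effect_matrix = np.asarray(self.effect_matrix, dtype=float)
        self.trait_corr = np.asarray(self.trait_corr, dtype=float)
        if self.effect_matrix.shape != (5, 5):
            raise ValueError("effect_matrix must be 5 traits x 5 kinematic parameters")
        if self.trait_corr.shape != (5, 5):
            raise ValueError("trait_corr must be 5x5")
        if self.n_frames < 75:
            raise ValueError("need at least 75 frames for the full pipeline")
        if self.noise_sd < 0 or self.score_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")

    @property
    def base_params(self) -> np.ndarray:
        return np.array(
            [self.arm_swing, self.torso_sway, self.stride, self.gait_period, self.head_bob]
        )


def kinematic_parameters(config: SyntheticConfig, latent: np.ndarray) -> np.ndarray:
    """Per-subject kinematic parameters: base + effects . latent, clipped.

    Amplitudes are clipped at 0; the gait period is kept within [12, 40]
    frames so at least one full stride fits in the analysis window.
    """
    effects = config.effect_scale * config.effect_matrix
    params = config.base_params[None, :] + latent @ effects
    period_i = KINEMATIC_PARAMS.index("gait_period")
    params = np.clip(params, 0.0, None)
    params[:, period_i] = np.clip(params[:, period_i], 12.0, 40.0)
    return params


def generate_gait_sequence(
    params: np.ndarray | dict[str, float],
    config: SyntheticConfig,
    rng: np.random.Generator,
    subject_id: str = "synthetic",
) -> GaitSequence:
    """One walking sequence from kinematic parameters.

    Phase advances at 2*pi / gait_period per frame.  Right limbs follow
    +sin, left limbs -sin (antiphase); arms are counter-phased to their
    same-side leg.  Elbows and knees move at half the wrist/ankle
    amplitude, foot points ride with their ankle, the upper body sways
    laterally and head points bob vertically at double the stride
    frequency.
    """
    if isinstance(params, dict):
        params = np.array([params[k] for k in KINEMATIC_PARAMS])
    arm, sway, stride, period, bob = params
    n = config.n_frames
    phase = 2 * np.pi * np.arange(n) / period
    s = np.sin(phase)
    s2 = np.sin(2 * phase)

    xy = np.empty((n, 25, 2))
    for k, (bx, by) in DEFAULT_BASE_POSE.items():
        xy[:, k, 0] = bx
        xy[:, k, 1] = by

    # legs: right ankle leads with +sin, left in antiphase
    for ankle, knee, foot_pts, sign in ((11, 10, (22, 23, 24), +1), (14, 13, (19, 20, 21), -1)):
        xy[:, ankle, 0] += sign * 0.5 * stride * s
        xy[:, knee, 0] += sign * 0.25 * stride * s
        for fp in foot_pts:
            xy[:, fp, 0] += sign * 0.5 * stride * s
    # arms: counter-phase to same-side leg
    for wrist, elbow, sign in ((4, 3, -1), (7, 6, +1)):
        xy[:, wrist, 0] += sign * arm * s
        xy[:, elbow, 0] += sign * 0.5 * arm * s
    # torso sway: neck, head and shoulders drift laterally at stride frequency
    for upper in (0, 1, 2, 5, 15, 16, 17, 18):
        xy[:, upper, 0] += sway * s
    # head bob: vertical, twice per stride (one bob per step)
    for head in (0, 15, 16, 17, 18):
        xy[:, head, 1] += bob * s2

    if config.noise_sd > 0:
        xy += rng.normal(0.0, config.noise_sd, size=xy.shape)
    conf = np.clip(rng.normal(0.9, 0.03, size=(n, 25)), 0.0, 1.0)
    return GaitSequence(subject_id, xy, conf)


def generate_scores(
    config: SyntheticConfig, latent: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """BFI-44-range subscale sums from latent traits plus score noise."""
    cols = {}
    for i, trait in enumerate(TRAITS):
        lo, hi = SCORE_RANGES[trait]
        raw = (
            SCORE_CENTERS[trait]
            + SCORE_SLOPES[trait] * latent[:, i]
            + rng.normal(0.0, config.score_noise_sd, size=latent.shape[0])
        )
        cols[trait] = np.clip(np.round(raw), lo, hi).astype(int)
    return pd.DataFrame(cols)


def generate_cohort(
    config: SyntheticConfig, with_sequences: bool = True
) -> tuple[list[GaitSequence], pd.DataFrame, pd.DataFrame]:
    """Generate sequences, scale scores and ground-truth latent parameters.

    Returns ``(sequences, scores, truth)``: ``truth`` holds the latent
    trait values (``latent_<trait>``) and realized kinematic parameters
    per subject.  Deterministic given ``config.seed``.  With
    ``with_sequences=False`` the sequence list is empty (scores-only
    cohorts for psychometric structure checks).
    """
    rng = np.random.default_rng(config.seed)
    cov = config.trait_corr
    latent = rng.multivariate_normal(np.zeros(5), cov, size=config.n_subjects)
    scores = generate_scores(config, latent, rng)
    params = kinematic_parameters(config, latent)
    sequences: list[GaitSequence] = []
    if with_sequences:
        for i in range(config.n_subjects):
            sequences.append(
                generate_gait_sequence(params[i], config, rng, subject_id=f"S{i:04d}")
            )
    truth = pd.DataFrame(
        np.hstack([latent, params]),
        columns=[f"latent_{t}" for t in TRAITS] + list(KINEMATIC_PARAMS),
    )
    scores.insert(0, "subject_id", [f"S{i:04d}" for i in range(config.n_subjects)])
    truth.insert(0, "subject_id", scores["subject_id"])
    return sequences, scores, truth
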