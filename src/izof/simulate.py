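"""Synthetic cohort generator with known ground truth.

The generative model mirrors the repeated-measures design the analysis
assumes: each participant carries a latent optimal anxiety triplet mu
(one value per subscale, drawn from the cohort distribution and clipped
to the 9-36 instrument range) and a true optimal band mu ± half-width.
On every occasion the reported intensity fluctuates around mu
(within-person state noise, rounded to the integer instrument scale),
and the latent performance declines linearly with the mean distance of
the three intensities from their true bands. A panel of judges observes
the performance with independent noise; the recorded score is the
trimmed panel aggregate.

Cohort-level defaults are calibrated to the descriptive anchors of a
30-pianist study population (zone centers CA 18.0 ± 4.9, SA 17.3 ± 4.8,
SC 20.9 ± 5.5; 4 recalled + 1 predicted occasion; 7 judges). The true
band half-width defaults to state_sd/2 so the M ± ½SD estimator is
consistent under the model, which makes parameter recovery a fair test
of the estimator rather than of a misspecified target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .data_model import (
    SUBSCALES,
    Cohort,
    PerformanceOccasion,
    Phase,
    SubscaleTriplet,
)
from .errors import AlignmentError, ConfigurationError
from .zones import Zone, ZoneSet

__all__ = ["GeneratorConfig", "LatentPianist", "generate", "recovery_error"]

_DEFAULT_CENTER_MEAN = {"ca": 18.0, "sa": 17.3, "sc": 20.9}
_DEFAULT_CENTER_SD = {"ca": 4.9, "sa": 4.8, "sc": 5.5}


@dataclass(frozen=True)
class GeneratorConfig:
    """Simulation parameters; defaults reproduce the study conditions."""

    n_participants: int = 30
    n_recalled: int = 4
    n_predicted: int = 1
    center_mean: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CENTER_MEAN)
    )
    center_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CENTER_SD)
    )
    state_sd: float = 2.6              # within-person occasion fluctuation
    true_zone_halfwidth: float = 1.3   # = state_sd / 2 by default
    base_score: float = 93.0           # performance with all subscales in-band
    penalty_beta: float = 2.0          # score units lost per unit mean distance
    score_noise_sd: float = 1.0
    n_judges: int = 7
    judge_noise_sd: float = 2.0
    subscale_corr: Optional[Sequence[Sequence[float]]] = None  # 3x3; None = identity
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be >= 0")
        if self.n_recalled < 2:
            raise ConfigurationError("n_recalled must be >= 2 (zone estimability)")
        if self.n_predicted < 0:
            raise ConfigurationError("n_predicted must be >= 0")
        if self.n_judges < 3:
            raise ConfigurationError("n_judges must be >= 3 (trimming)")
        for name in ("state_sd", "true_zone_halfwidth", "score_noise_sd",
                     "judge_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for mapping, name in ((self.center_mean, "center_mean"),
                              (self.center_sd, "center_sd")):
            for s in SUBSCALES:
                if s not in mapping:
                    raise ConfigurationError(f"{name} missing subscale {s!r}")
            if name == "center_sd" and any(mapping[s] < 0 for s in SUBSCALES):
                raise ConfigurationError("center_sd values must be >= 0")
        if not 1.0 <= self.base_score <= 100.0:
            raise ConfigurationError("base_score must be in [1, 100]")
        if self.subscale_corr is not None:
            c = np.asarray(self.subscale_corr, dtype=float)
            if c.shape != (3, 3):
                raise ConfigurationError("subscale_corr must be a 3x3 matrix")
            if not np.allclose(c, c.T) or np.any(np.diag(c) != 1.0):
                raise ConfigurationError(
                    "subscale_corr must be symmetric with unit diagonal"
                )


@dataclass(frozen=True)
class LatentPianist:
    """Ground truth for one simulated participant."""

    participant_id: str
    mu: tuple[float, float, float]      # latent optimal (ca, sa, sc)
    true_zone: ZoneSet

    def mu_for(self, subscale: str) -> float:
        return self.mu[SUBSCALES.index(subscale)]


def _trimmed_mean_rows(panels: np.ndarray) -> np.ndarray:
    """Trim one score per end and average, row-wise (..., n_judges)."""
    srt = np.sort(panels, axis=-1)
    return srt[..., 1:-1].mean(axis=-1)


def generate(config: GeneratorConfig) -> tuple[Cohort, list[LatentPianist]]:
    """Draw a cohort and its ground-truth latents; same seed, same cohort."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    P = config.n_participants
    O = config.n_recalled + config.n_predicted
    J = config.n_judges
    hw = config.true_zone_halfwidth

    means = np.array([config.center_mean[s] for s in SUBSCALES])
    sds = np.array([config.center_sd[s] for s in SUBSCALES])
    mu = np.clip(rng.normal(means, sds, size=(P, 3)), 9.0, 36.0)

    if config.subscale_corr is None:
        chol = np.eye(3)
    else:
        chol = np.linalg.cholesky(np.asarray(config.subscale_corr, dtype=float))
    state_noise = rng.standard_normal((P, O, 3)) @ chol.T * config.state_sd
    intensities = np.rint(np.clip(mu[:, None, :] + state_noise, 9, 36)).astype(int)

    dist = np.maximum(0.0, np.abs(intensities - mu[:, None, :]) - hw)
    perf = (
        config.base_score
        - config.penalty_beta * dist.mean(axis=2)
        + rng.normal(0.0, config.score_noise_sd, size=(P, O))
    )
    perf = np.clip(perf, 1.0, 100.0)
    judges = np.rint(
        np.clip(perf[:, :, None] + rng.normal(0.0, config.judge_noise_sd,
                                              size=(P, O, J)), 1, 100)
    ).astype(int)
    scores = _trimmed_mean_rows(judges.astype(float))

    id_width = max(2, len(str(P)))
    occasions: list[PerformanceOccasion] = []
    latents: list[LatentPianist] = []
    for p in range(P):
        pid = f"P{p + 1:0{id_width}d}"
        for o in range(O):
            if o < config.n_recalled:
                occ_id, phase = f"R{o + 1}", Phase.RECALLED
            else:
                occ_id, phase = f"J{o - config.n_recalled + 1}", Phase.PREDICTED
            ca, sa, sc = (int(v) for v in intensities[p, o])
            occasions.append(
                PerformanceOccasion(
                    participant_id=pid,
                    occasion_id=occ_id,
                    phase=phase,
                    triplet=SubscaleTriplet(ca=ca, sa=sa, sc=sc),
                    score=float(scores[p, o]),
                    judge_scores=tuple(int(v) for v in judges[p, o]),
                )
            )
        mu_t = tuple(float(v) for v in mu[p])
        latents.append(
            LatentPianist(
                participant_id=pid,
                mu=mu_t,  # type: ignore[arg-type]
                true_zone=ZoneSet(
                    participant_id=pid,
                    ca=Zone(mu_t[0], hw),
                    sa=Zone(mu_t[1], hw),
                    sc=Zone(mu_t[2], hw),
                    n_occasions_used=config.n_recalled,
                ),
            )
        )
    return Cohort(occasions), latents


def recovery_error(
    zonesets: Mapping[str, ZoneSet],
    latents: Sequence[LatentPianist],
) -> dict[str, float]:
    """Per-subscale mean absolute error of estimated zone centers against
    the latent optima — the parameter-recovery diagnostic."""
    if set(zonesets) != {lat.participant_id for lat in latents}:
        raise AlignmentError(
            "zone sets and latents cover different participant sets"
        )
    if not latents:
        raise AlignmentError("no participants to compare")
    out: dict[str, float] = {}
    for i, s in enumerate(SUBSCALES):
        errs = [
            abs(zonesets[lat.participant_id].zone(s).center - lat.mu[i])
            for lat in latents
        ]
        out[s] = float(np.mean(errs))
    return out
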