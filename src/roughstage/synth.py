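"""Synthetic colorectal-cancer information systems.

The generator emulates the statistical structure the pipeline assumes:

* clinical covariates — age uniform over [28, 78], gender in {1, 2}, tumour
  location in {1..4}, two binary adjuvant-treatment flags;
* microarray-style gene expression — each gene has a baseline level inside a
  printed probe range; patients scatter tightly (Gaussian, sd
  ``noise_sd``) around that level, and the level is shifted additively by
  ``effect_size`` per stage step.  The tight within-stage spread is what
  real log-scale probe intensities show within a biological group and is
  what lets an α-cut transitive closure recover a handful of expression
  classes per gene rather than chaining the whole cohort into one class;
* follow-up — Weibull(shape, scale) event times, with the scale multiplied
  by a decreasing per-stage factor so later stages fail earlier, and a
  configurable right-censoring fraction (censoring times drawn uniformly
  below the latent event time).

Identical seeds give byte-identical systems.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .infosys import AttributeSpec, InformationSystem

__all__ = ["generate_synthetic", "GENE_RANGES", "STAGE_SCALE_FACTORS"]

#: (low, high) plausible ranges of the 17 probe attributes of the packaged
#: 20-patient sample; recycled when more genes are requested.
GENE_RANGES: tuple[tuple[float, float], ...] = (
    (3.31, 5.32), (2.76, 7.26), (3.41, 6.82), (2.79, 6.01), (5.23, 8.21),
    (4.00, 5.31), (3.32, 10.35), (5.01, 8.31), (2.86, 5.09), (3.51, 6.56),
    (3.38, 6.23), (3.93, 6.51), (2.91, 8.03), (4.03, 7.61), (3.95, 7.81),
    (3.45, 5.75), (3.99, 8.52),
)

#: Multiplier on the Weibull scale per Dukes stage 0..3: later stages fail
#: earlier, mirroring the ordering of stage-stratified survival.
STAGE_SCALE_FACTORS: tuple[float, ...] = (1.0, 0.8, 0.6, 0.5)


class ParameterError(ValueError):
    """An invalid generator parameter."""


def generate_synthetic(
    n_objects: int,
    n_genes: int = 17,
    stage_probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    effect_size: float = 0.8,
    weibull_shape: float = 1.5,
    weibull_scale: float = 60.0,
    censor_frac: float = 0.3,
    seed: int = 0,
    noise_sd: float = 0.05,
    stage_scale_factors: Sequence[float] = STAGE_SCALE_FACTORS,
) -> InformationSystem:
    """Generate a synthetic patient information system.

    Parameters
    ----------
    n_objects, n_genes : int
        Numbers of patients and gene-expression attributes (each ≥ 1).
    stage_probs : 4-vector
        Marginal probabilities of Dukes stages 0..3; must sum to 1.
    effect_size : float
        Additive shift of a gene's expression level per stage step.  Each
        gene is assigned a random direction, so some genes rise and some
        fall with stage.  0 removes all stage signal from the genes.
    weibull_shape, weibull_scale : float
        Event-time distribution for stage 0; ``weibull_scale`` is in months.
    censor_frac : float in [0, 1]
        Expected fraction of right-censored records; a censored patient's
        follow-up time is uniform below the latent event time.
    seed : int
        Seeds all randomness; identical seeds reproduce the system exactly.
    noise_sd : float
        Within-stage Gaussian spread of each gene around its level.
    stage_scale_factors : 4-vector
        Per-stage multipliers on the Weibull scale.

    Returns
    -------
    InformationSystem
        Columns: Age, Gender, LOC, AdjRadio, AdjChem, gene columns G1..Gk,
        DFS (time, months), event, d (stage).
    """
    stage_probs = np.asarray(stage_probs, dtype=float)
    if stage_probs.shape != (4,) or np.any(stage_probs < 0):
        raise ParameterError("stage_probs must be 4 nonnegative probabilities")
    if abs(stage_probs.sum() - 1.0) > 1e-9:
        raise ParameterError(
            f"stage_probs must sum to 1 (got {stage_probs.sum()!r})"
        )
    if n_objects < 1 or n_genes < 1:
        raise ParameterError("counts must be >= 1")
    if not (0.0 <= censor_frac <= 1.0):
        raise ParameterError("censor_frac must be in [0, 1]")
    if weibull_shape <= 0 or weibull_scale <= 0:
        raise ParameterError("Weibull shape and scale must be positive")
    factors = np.asarray(stage_scale_factors, dtype=float)
    if factors.shape != (4,) or np.any(factors <= 0):
        raise ParameterError("stage_scale_factors must be 4 positive reals")

    rng = np.random.default_rng(seed)
    stage = rng.choice(4, size=n_objects, p=stage_probs)

    age = np.round(rng.uniform(28, 78, size=n_objects))
    gender = rng.integers(1, 3, size=n_objects).astype(float)
    location = rng.integers(1, 5, size=n_objects).astype(float)
    adj_radio = rng.integers(0, 2, size=n_objects).astype(float)
    adj_chem = rng.integers(0, 2, size=n_objects).astype(float)

    genes = np.empty((n_objects, n_genes))
    for g in range(n_genes):
        lo, hi = GENE_RANGES[g % len(GENE_RANGES)]
        width = hi - lo
        # keep the baseline plus up to 3 stage steps inside the printed range
        lo_eff = lo + 0.05 * width
        hi_eff = hi - 0.05 * width - 3.0 * abs(effect_size)
        baseline = rng.uniform(lo_eff, max(hi_eff, lo_eff))
        direction = rng.choice([-1.0, 1.0])
        shift = effect_size * stage
        if direction < 0:  # descending genes start high instead
            shift = effect_size * (3 - stage)
        genes[:, g] = baseline + shift + rng.normal(0.0, noise_sd, n_objects)

    latent = factors[stage] * weibull_scale * rng.weibull(weibull_shape, n_objects)
    latent = np.maximum(latent, 1e-6)
    censored = rng.random(n_objects) < censor_frac
    time = np.where(censored, rng.uniform(0.0, 1.0, n_objects) * latent, latent)
    time = np.maximum(time, 1e-6)
    event = (~censored).astype(float)

    attrs = [
        AttributeSpec("Age", "numeric"),
        AttributeSpec("Gender", "categorical"),
        AttributeSpec("LOC", "categorical"),
        AttributeSpec("AdjRadio", "categorical"),
        AttributeSpec("AdjChem", "categorical"),
    ]
    cols = [age, gender, location, adj_radio, adj_chem]
    for g in range(n_genes):
        lo, hi = GENE_RANGES[g % len(GENE_RANGES)]
        attrs.append(AttributeSpec(f"G{g + 1}", "numeric", (lo, hi)))
        cols.append(genes[:, g])
    attrs += [
        AttributeSpec("DFS", "time"),
        AttributeSpec("event", "event"),
        AttributeSpec("d", "decision"),
    ]
    cols += [time, event, stage.astype(float)]

    return InformationSystem(
        object_ids=[f"s{i + 1}" for i in range(n_objects)],
        attributes=attrs,
        values=np.column_stack(cols),
        decision_attribute="d",
        time_attribute="DFS",
        event_attribute="event",
    )
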