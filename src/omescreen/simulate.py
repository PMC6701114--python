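"""Synthetic merged tables with known planted structure.

The generator emulates the shape of real microbiome:immune cohort studies:
2-4 cohorts of a few dozen samples each, microbial relative abundances that
are zero-inflated and bounded in [0, 1], and positive continuous immune
readouts.  Null microbes are independent of every immune feature; *planted*
microbes are per-cohort linear functions of one immune partner plus Gaussian
noise, clipped into the unit interval, so the generating model matches the
fitted linear model and parameter recovery is well defined.

The returned truth record identifies every planted pair and its per-cohort
slopes, which suffices to compute realized power and false-discovery
proportion for any screen run on the generated table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GenerationError, ValidationError
from .screen import TopTable
from .tables import IMMUNE, MICROBE, FeatureMeta, MergedTable


@dataclass(frozen=True)
class PlantedPair:
    """One planted microbe-immune association.

    ``slopes`` maps each cohort label to the linear slope of the microbe on
    its immune partner in that cohort (0 plants no association there);
    ``intercept`` is the cohort-independent baseline abundance and
    ``noise_sd`` the Gaussian residual scale, both on the relative-abundance
    scale.
    """

    microbe: int
    immune: int
    slopes: dict[str, float]
    noise_sd: float = 0.02
    intercept: float = 0.1


@dataclass
class SyntheticSpec:
    """Conditions for one synthetic cohort study.

    Defaults mirror a small two-cohort fecal-sample study: ~35 samples split
    across cohorts, zero-inflated null microbes (a null microbe is 0 with
    probability ``zero_inflation_prob``, otherwise Beta-distributed at low
    abundance), and immune readouts drawn i.i.d. log-normal on a unit-free
    positive scale.  The default scale (mu=-0.7, sigma=0.5, median ~0.5)
    keeps x below the clipping point (1 - intercept)/slope at roughly three
    log-normal sigmas for planted slopes up to ~0.4, so boundary clipping —
    which would bias slope recovery — is rare under the defaults.
    """

    cohorts: dict[str, int] = field(
        default_factory=lambda: {"A": 18, "B": 17})
    n_microbes: int = 10
    n_immune: int = 5
    planted: list[PlantedPair] = field(default_factory=list)
    zero_inflation_prob: float = 0.3
    immune_mu: float = -0.7
    immune_sigma: float = 0.5
    microbe_beta_a: float = 1.5
    microbe_beta_b: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.zero_inflation_prob < 1.0):
            raise ValidationError("zero_inflation_prob must lie in [0, 1)")
        if len(self.cohorts) < 2:
            raise ValidationError("at least 2 cohorts required")
        for pp in self.planted:
            if not (0 <= pp.microbe < self.n_microbes):
                raise ValidationError(f"planted microbe index {pp.microbe} out of range")
            if not (0 <= pp.immune < self.n_immune):
                raise ValidationError(f"planted immune index {pp.immune} out of range")
            if not all(np.isfinite(list(pp.slopes.values()))):
                raise ValidationError("planted slopes must be finite")
            if set(pp.slopes) - set(self.cohorts):
                raise ValidationError("planted slope map names an unknown cohort")

    @property
    def n_samples(self) -> int:
        return sum(self.cohorts.values())


def _microbe_name(i: int) -> str:
    return f"Mb_{i + 1}"


def _immune_name(i: int) -> str:
    return f"IR_{i + 1}"


def generate_dataset(spec: SyntheticSpec) -> tuple[MergedTable, dict]:
    """Generate a merged table plus truth record, reproducibly from the seed.

    Raises :class:`GenerationError` when a planted feature has more than half
    its values clipped at the [0, 1] boundary — effect sizes that large are
    unrealistic for relative abundances and break the linear generating model.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    cohort_labels = np.concatenate(
        [np.repeat(lab, cnt) for lab, cnt in spec.cohorts.items()])
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    immune = rng.lognormal(mean=spec.immune_mu, sigma=spec.immune_sigma,
                           size=(n, spec.n_immune))

    microbes = np.empty((n, spec.n_microbes))
    for j in range(spec.n_microbes):
        nonzero = rng.random(n) >= spec.zero_inflation_prob
        abund = rng.beta(spec.microbe_beta_a, spec.microbe_beta_b, size=n)
        microbes[:, j] = np.where(nonzero, abund, 0.0)

    planted_truth = []
    for pp in spec.planted:
        x = immune[:, pp.immune]
        y = np.full(n, float(pp.intercept))
        for lab, slope in pp.slopes.items():
            mask = cohort_labels == lab
            y[mask] += slope * x[mask]
        y += rng.normal(0.0, pp.noise_sd, size=n)
        clipped = (y < 0.0) | (y > 1.0)
        frac = float(clipped.mean())
        if frac > 0.5:
            raise GenerationError(
                f"planted feature {_microbe_name(pp.microbe)}: {frac:.0%} of "
                "values clipped at [0, 1]; effect sizes unrealistic for the "
                "unit interval"
            )
        microbes[:, pp.microbe] = np.clip(y, 0.0, 1.0)
        planted_truth.append({
            "microbe": _microbe_name(pp.microbe),
            "immune": _immune_name(pp.immune),
            "slopes": dict(pp.slopes),
            "noise_sd": pp.noise_sd,
            "intercept": pp.intercept,
            "clipped_fraction": frac,
        })

    features = (
        [FeatureMeta(_microbe_name(j), MICROBE, "relative abundance")
         for j in range(spec.n_microbes)]
        + [FeatureMeta(_immune_name(j), IMMUNE, "arbitrary positive units")
           for j in range(spec.n_immune)]
    )
    values = pd.DataFrame(
        np.hstack([microbes, immune]),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=[f.name for f in features],
    )
    cohorts = pd.Series(cohort_labels, index=values.index, name="cohort")
    table = MergedTable(values=values, cohorts=cohorts, features=features)
    truth = {
        "seed": spec.seed,
        "cohorts": dict(spec.cohorts),
        "planted": planted_truth,
    }
    return table, truth


def null_dataset(spec: SyntheticSpec) -> MergedTable:
    """A table with no planted associations, for type-I calibration."""
    if spec.planted:
        spec = SyntheticSpec(
            cohorts=dict(spec.cohorts), n_microbes=spec.n_microbes,
            n_immune=spec.n_immune, planted=[],
            zero_inflation_prob=spec.zero_inflation_prob,
            immune_mu=spec.immune_mu, immune_sigma=spec.immune_sigma,
            microbe_beta_a=spec.microbe_beta_a,
            microbe_beta_b=spec.microbe_beta_b, seed=spec.seed,
        )
    table, _ = generate_dataset(spec)
    return table


def evaluate_screen(top: TopTable, truth: dict) -> dict:
    """Realized power and false-discovery proportion of a screen vs truth.

    A surfaced row is a true positive when its (microbe, immune) pair was
    planted with a nonzero slope in at least one cohort.
    """
    planted_pairs = {
        (t["microbe"], t["immune"])
        for t in truth["planted"]
        if any(s != 0.0 for s in t["slopes"].values())
    }
    surfaced = {(r.microbe, r.immune) for r in top.rows}
    tp = len(surfaced & planted_pairs)
    fp = len(surfaced - planted_pairs)
    return {
        "n_planted": len(planted_pairs),
        "n_surfaced": len(surfaced),
        "true_positives": tp,
        "false_positives": fp,
        "power": tp / len(planted_pairs) if planted_pairs else float("nan"),
        "fdp": fp / len(surfaced) if surfaced else 0.0,
    }
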