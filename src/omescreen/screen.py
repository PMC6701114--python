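"""Drive all pairwise fits, adjust for multiple testing, build the top table.

Every (microbe, immune) feature pair gets one regression attempt, in
deterministic manifest order (microbes outer, immune inner).  Pairs whose
fit is degenerate (singular design, constant response, perfect fit) are
recorded with a reason and excluded from the screen; the Benjamini-Hochberg
adjustment runs over the p-values of all non-degenerate fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractError
from .regress import PairFit, fit_pair, glyph_segments
from .tables import MergedTable, RunConfig, pairwise_complete
from .errors import DegenerateFitError, InsufficientDataError

logger = logging.getLogger("omescreen")


@dataclass(frozen=True)
class SkippedPair:
    microbe: str
    immune: str
    reason: str


@dataclass
class ScreenResult:
    """All per-pair fits from one screen plus skipped-pair bookkeeping."""

    fits: list[PairFit]
    skipped: list[SkippedPair]

    @property
    def n_attempted(self) -> int:
        return len(self.fits) + len(self.skipped)


def screen_all_pairs(table: MergedTable, config: RunConfig) -> ScreenResult:
    """Attempt one fit per (microbe, immune) pair.

    The attempted-fit count always equals #microbes x #immune; degenerate or
    data-starved pairs are skipped with a logged reason rather than failing
    the run.
    """
    config.check_against(table)
    microbes = table.microbe_names
    immunes = table.immune_names
    if not microbes or not immunes:
        raise ConfigurationError(
            f"screen needs features in both omes "
            f"(microbes={len(microbes)}, immune={len(immunes)})"
        )
    cohorts_all = table.cohorts.to_numpy()
    fits: list[PairFit] = []
    skipped: list[SkippedPair] = []
    for mb in microbes:
        y_all = table.values[mb].to_numpy(dtype=float)
        for ir in immunes:
            x_all = table.values[ir].to_numpy(dtype=float)
            y, x, coh = pairwise_complete(y_all, x_all, cohorts_all)
            try:
                fit = fit_pair(y, x, coh, config.reference_cohort,
                               microbe=mb, immune=ir)
            except DegenerateFitError as exc:
                skipped.append(SkippedPair(mb, ir, exc.reason))
                logger.warning("skipped pair (%s, %s): %s", mb, ir, exc)
                continue
            except InsufficientDataError as exc:
                skipped.append(SkippedPair(mb, ir, "insufficient_data"))
                logger.warning("skipped pair (%s, %s): %s", mb, ir, exc)
                continue
            if fit.degenerate_perfect:
                skipped.append(SkippedPair(mb, ir, "perfect_fit"))
                logger.warning(
                    "skipped pair (%s, %s): zero residual sum of squares", mb, ir
                )
                continue
            fits.append(fit)
    logger.info(
        "screen: %d pairs attempted, %d fit, %d skipped",
        len(fits) + len(skipped), len(fits), len(skipped),
    )
    return ScreenResult(fits=fits, skipped=skipped)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    q_(i) = min over j >= i of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ContractError("p must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ContractError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


@dataclass
class TopTableRow:
    key: int
    microbe: str
    immune: str
    F: float
    p: float
    pAdj: float
    interaction_p: dict[str, float] | None
    max_influence: float | None
    fit: PairFit


@dataclass
class TopTable:
    """Threshold-filtered, p-sorted pair results with configured metrics."""

    rows: list[TopTableRow]
    m: int  # number of non-degenerate fits the BH adjustment ran over
    config: RunConfig

    def __len__(self) -> int:
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular view with exactly the configured metric columns."""
        cols = self.config.metric_columns
        records = []
        for r in self.rows:
            rec: dict = {"key": r.key, "microbe": r.microbe, "immune": r.immune}
            if "F" in cols:
                rec["F"] = r.F
            if "p" in cols:
                rec["p"] = r.p
            if "pAdj" in cols:
                rec["pAdj"] = r.pAdj
            if "interaction_p" in cols and r.interaction_p is not None:
                for cohort, pv in r.interaction_p.items():
                    rec[f"interactionP_{cohort}"] = pv
            if "max_influence" in cols:
                rec["maxInfluence"] = r.max_influence
            records.append(rec)
        df = pd.DataFrame.from_records(records)
        if df.empty:
            base = ["key", "microbe", "immune"]
            base += [c for c in ("F", "p", "pAdj") if c in cols]
            if "max_influence" in cols:
                base.append("maxInfluence")
            df = pd.DataFrame(columns=base)
        return df


def build_top_table(fits: list[PairFit], config: RunConfig) -> TopTable:
    """Adjust, threshold, sort and key the screened pairs.

    BH runs over all non-degenerate fits (m = len(fits)).  A pair is retained
    when its p (threshold_type ``raw_p``) or BH-adjusted p (``fdr_p``) is
    strictly below the configured threshold.  Rows are sorted by p ascending
    with (microbe, immune) lexicographic tie-break, then keyed 1..R.
    """
    if not fits:
        raise ContractError("build_top_table requires at least one fit")
    p = np.array([f.p for f in fits])
    padj = bh_adjust(p)
    crit = p if config.threshold_type == "raw_p" else padj
    kept = [i for i in range(len(fits)) if crit[i] < config.threshold_value]
    kept.sort(key=lambda i: (p[i], fits[i].microbe, fits[i].immune))
    rows = []
    for key, i in enumerate(kept, start=1):
        f = fits[i]
        rows.append(
            TopTableRow(
                key=key, microbe=f.microbe, immune=f.immune,
                F=f.F, p=float(p[i]), pAdj=float(padj[i]),
                interaction_p=(dict(f.interaction_p)
                               if "interaction_p" in config.metric_columns else None),
                max_influence=(f.max_influence
                               if "max_influence" in config.metric_columns else None),
                fit=f,
            )
        )
    if not rows:
        logger.info("top table empty at %s < %g",
                    config.threshold_type, config.threshold_value)
    else:
        logger.info("top table: %d rows surfaced (m=%d)", len(rows), len(fits))
    return TopTable(rows=rows, m=len(fits), config=config)


@dataclass(frozen=True)
class NetworkNode:
    name: str
    ome: str
    degree: int


@dataclass
class NetworkSummary:
    """Analyte nodes and pair edges summarizing a top table.

    Each node is an analyte tagged with its ome; each edge is one top-table
    row, carrying the row key, so edges and rows are 1:1.
    """

    nodes: list[NetworkNode] = field(default_factory=list)
    edges: list[tuple[str, str, int]] = field(default_factory=list)


def network_summary(table: TopTable) -> NetworkSummary:
    """Collapse a top table into its analyte network (degree = incident edges)."""
    degree: dict[str, int] = {}
    ome: dict[str, str] = {}
    edges = []
    for r in table.rows:
        degree[r.microbe] = degree.get(r.microbe, 0) + 1
        degree[r.immune] = degree.get(r.immune, 0) + 1
        ome.setdefault(r.microbe, "microbe")
        ome.setdefault(r.immune, "immune")
        edges.append((r.microbe, r.immune, r.key))
    nodes = [NetworkNode(name, ome[name], degree[name]) for name in degree]
    return NetworkSummary(nodes=nodes, edges=edges)


def run_screen(table: MergedTable, config: RunConfig) -> tuple[ScreenResult, TopTable]:
    """Full pipeline: prevalence filter, immune transform, screen, top table."""
    config.check_against(table)
    if config.min_nonzero > 0:
        from .tables import prevalence_filter
        table = prevalence_filter(table, config.min_nonzero)
        logger.info("prevalence filter: %d microbes retained",
                    len(table.microbe_names))
    if config.immune_transform != "none":
        from .tables import apply_transform
        table = apply_transform(table, "immune", config.immune_transform)
        logger.info("applied %s transform to immune features",
                    config.immune_transform)
    result = screen_all_pairs(table, config)
    top = build_top_table(result.fits, config) if result.fits else TopTable(
        rows=[], m=0, config=config)
    return result, top


# re-export used by rendering code
__all__ = [
    "ScreenResult", "SkippedPair", "TopTable", "TopTableRow",
    "NetworkSummary", "NetworkNode",
    "screen_all_pairs", "bh_adjust", "build_top_table", "network_summary",
    "run_screen", "glyph_segments",
]
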