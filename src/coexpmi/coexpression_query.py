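"""User-facing coexpression computations.

Per-pair reports combine the Pearson coefficient r, the mutual information
MI (11 adaptive intervals by default), their percent ranks RoMI and Ror
from a prebuilt :class:`~coexpmi.rank_index.CoexpressionIndex`, the hybrid
score MIr, co-occurrence rates of present/absent detection calls, and
scatter data.  The comparison of RoMI with Ror separates four situations:

1. both high — strong linear (and hence nonlinear) coexpression;
2. RoMI high, Ror low — strong dependency invisible to a linear measure;
3. both low — no appreciable dependency;
4. RoMI low, Ror high — a spuriously large r, typically driven by probes
   absent in almost every sample (high absent-absent rate, zero
   present-present rate), with no real information shared.

The hybrid score for a query probe i and candidate j is

    MIr = beta * r_ij / max_{k!=i} r_ik  +  (1-beta) * MI_ij / max_{k!=i} MI_ik,

with beta ~ 0.5; the maxima run over the query's candidate set, so the best
candidate on both measures scores exactly 1.  Top-k queries return three
lists — by MI, by r and by MIr — over all candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .correlation_core import BinningConfig, pearson_r
from .errors import (
    InvalidValueError,
    LengthMismatchError,
    SelfPairError,
    UndefinedScoreError,
    UnknownProbeError,
)
from .expression_data import DetectionCallMatrix, ExpressionMatrix, ProbeAnnotation
from .rank_index import CoexpressionIndex

__all__ = [
    "CooccurrenceRates",
    "PairCorrelation",
    "RelatedGene",
    "RelatedGeneList",
    "cooccurrence_rates",
    "mir_score",
    "pair_report",
    "top_related",
    "scatter_export",
    "DEFAULT_BETA",
]

#: Mixing weight between the r term and the MI term of the hybrid score.
DEFAULT_BETA = 0.5


@dataclass(frozen=True)
class CooccurrenceRates:
    """Fractions of samples per present/absent call combination.

    Each rate is a fraction of *all* samples; samples with a marginal call
    in either probe are counted in none of the four, so the four rates sum
    to at most 1.
    """

    pp: float
    aa: float
    pa: float
    ap: float

    @property
    def total_coexpression(self) -> float:
        """pp + aa: the fraction of samples where both probes agree on
        detection.  The composite is reported alongside its parts because a
        high aa with pp = 0 signals jointly-silent probes, not coexpression."""
        return self.pp + self.aa


def cooccurrence_rates(calls_a, calls_b) -> CooccurrenceRates:
    """P/A co-occurrence rates of two detection-call vectors."""
    a = np.asarray(calls_a, dtype="<U1")
    b = np.asarray(calls_b, dtype="<U1")
    if a.size != b.size:
        raise LengthMismatchError(f"call vectors differ in length: {a.size} vs {b.size}")
    if a.size == 0:
        raise InvalidValueError("empty call vectors")
    n = a.size
    usable = (a != "M") & (b != "M")
    return CooccurrenceRates(
        pp=float(np.count_nonzero(usable & (a == "P") & (b == "P"))) / n,
        aa=float(np.count_nonzero(usable & (a == "A") & (b == "A"))) / n,
        pa=float(np.count_nonzero(usable & (a == "P") & (b == "A"))) / n,
        ap=float(np.count_nonzero(usable & (a == "A") & (b == "P"))) / n,
    )


@dataclass(frozen=True)
class PairCorrelation:
    """Everything reported for one probe pair."""

    probe_a: str
    probe_b: str
    r: float
    mi: float
    ro_mi: int | None = None
    ro_r: int | None = None
    mir: float | None = None
    rates: CooccurrenceRates | None = None

    def to_dict(self) -> dict:
        out = {
            "probe_a": self.probe_a,
            "probe_b": self.probe_b,
            "r": self.r,
            "mi": self.mi,
            "ro_mi": self.ro_mi,
            "ro_r": self.ro_r,
            "mir": self.mir,
        }
        if self.rates is not None:
            out["rates"] = {
                "pp": self.rates.pp, "aa": self.rates.aa,
                "pa": self.rates.pa, "ap": self.rates.ap,
                "total_coexpression": self.rates.total_coexpression,
            }
        return out


def mir_score(r: float, mi: float, max_r: float, max_mi: float,
              beta: float = DEFAULT_BETA) -> float:
    """Hybrid MIr score: beta * r/max_r + (1-beta) * mi/max_mi.

    ``max_r`` and ``max_mi`` must be the maxima over the query probe's
    candidate set (query excluded); they normalise both measures onto a
    common scale before mixing.
    """
    if not 0.0 <= beta <= 1.0:
        raise InvalidValueError(f"beta must be in [0, 1], got {beta}")
    if max_r <= 0 or max_mi <= 0:
        raise UndefinedScoreError(
            f"normalisation maxima must be positive, got max_r={max_r}, max_mi={max_mi}"
        )
    return beta * r / max_r + (1.0 - beta) * mi / max_mi


def _candidate_scores(matrix: ExpressionMatrix, probe: str,
                      binning: BinningConfig,
                      use_abs_r: bool) -> tuple[list[str], np.ndarray, np.ndarray]:
    """r and MI of the query probe against every other probe."""
    x = matrix.vector(probe)
    others = [p for p in matrix.probe_ids if p != probe]
    if not others:
        raise InvalidValueError("matrix has no candidate probes besides the query")
    scheme_x = binning.bins(x)
    r_vals = np.empty(len(others))
    mi_vals = np.empty(len(others))
    from .correlation_core import joint_counts, mutual_information  # local to avoid cycle noise

    for i, p in enumerate(others):
        y = matrix.vector(p)
        r_vals[i] = pearson_r(x, y)
        mi_vals[i] = mutual_information(joint_counts(scheme_x, binning.bins(y)))
    if use_abs_r:
        r_vals = np.abs(r_vals)
    return others, r_vals, mi_vals


def pair_report(matrix: ExpressionMatrix, probe_a: str, probe_b: str,
                index: CoexpressionIndex | None = None,
                calls: DetectionCallMatrix | None = None,
                binning: BinningConfig | None = None,
                beta: float = DEFAULT_BETA,
                use_abs_r: bool = False) -> PairCorrelation:
    """Full correlation report for one probe pair.

    r and MI always; RoMI/Ror when a matching ``index`` is supplied (its
    fingerprint is checked against the matrix); MIr normalised over probe
    A's candidate set; P/A co-occurrence rates when ``calls`` accompany the
    matrix.  By default r enters MIr signed; ``use_abs_r`` switches the MIr
    numerator and maxima to magnitudes for consistency with the |r|-based
    Ror.
    """
    if probe_a == probe_b:
        raise SelfPairError(f"probe {probe_a!r} paired with itself; MIr excludes the query")
    cfg = binning or BinningConfig()
    x, y = matrix.vector(probe_a), matrix.vector(probe_b)
    r = pearson_r(x, y)
    mi = cfg.mi(x, y)

    ro_mi = ro_r = None
    if index is not None:
        index.check_matrix(matrix)
        ro_mi = index.mi.rank(mi)
        ro_r = index.r.rank(r)

    candidates, r_all, mi_all = _candidate_scores(matrix, probe_a, cfg, use_abs_r)
    pos = candidates.index(probe_b)
    mir = mir_score(r_all[pos], mi_all[pos], float(r_all.max()), float(mi_all.max()), beta)

    rates = None
    if calls is not None:
        calls.check_companion(matrix)
        rates = cooccurrence_rates(calls.vector(probe_a), calls.vector(probe_b))

    return PairCorrelation(probe_a=probe_a, probe_b=probe_b, r=r, mi=mi,
                           ro_mi=ro_mi, ro_r=ro_r, mir=mir, rates=rates)


@dataclass(frozen=True)
class RelatedGene:
    probe_id: str
    gene_symbol: str
    score: float


@dataclass(frozen=True)
class RelatedGeneList:
    """Top-k candidates for one query probe, from three perspectives.

    Lists are stored strongest-first; ties break by probe ID so results are
    deterministic.  The query probe itself is never a candidate.
    """

    query: str
    by_mi: list[RelatedGene]
    by_r: list[RelatedGene]
    by_mir: list[RelatedGene]


def top_related(matrix: ExpressionMatrix, probe: str, k: int = 10,
                beta: float = DEFAULT_BETA,
                binning: BinningConfig | None = None,
                annotation: ProbeAnnotation | None = None,
                use_abs_r: bool = False) -> RelatedGeneList:
    """The k most related probes to a query, by MI, by r and by MIr.

    Scores every candidate (all probes but the query), then sorts each
    perspective descending.  ``k`` larger than the candidate count returns
    them all.
    """
    if probe not in matrix.probe_ids:
        raise UnknownProbeError(f"unknown probe ID {probe!r}")
    if k < 1:
        raise InvalidValueError(f"k must be positive, got {k}")
    cfg = binning or BinningConfig()
    candidates, r_all, mi_all = _candidate_scores(matrix, probe, cfg, use_abs_r)
    mir_all = np.array([
        mir_score(r_all[i], mi_all[i], float(r_all.max()), float(mi_all.max()), beta)
        for i in range(len(candidates))
    ])

    def top(scores: np.ndarray) -> list[RelatedGene]:
        order = sorted(range(len(candidates)), key=lambda i: (-scores[i], candidates[i]))
        chosen = order[: min(k, len(candidates))]
        return [
            RelatedGene(
                probe_id=candidates[i],
                gene_symbol=(annotation.symbol(candidates[i], default=candidates[i])
                             if annotation else candidates[i]),
                score=float(scores[i]),
            )
            for i in chosen
        ]

    return RelatedGeneList(query=probe, by_mi=top(mi_all), by_r=top(r_all),
                           by_mir=top(mir_all))


def scatter_export(matrix: ExpressionMatrix, probe_a: str, probe_b: str,
                   path, plot_path=None) -> None:
    """Write the two probes' paired signal values as a two-column TSV.

    Rows are labelled by sample ID, columns ordered (probe_a, probe_b) —
    the data behind the scatter plot a coexpression browser would draw.
    ``plot_path`` additionally saves a PNG scatter via matplotlib.
    """
    x, y = matrix.vector(probe_a), matrix.vector(probe_b)
    lines = [f"sample_id\t{probe_a}\t{probe_b}"]
    lines += [f"{s}\t{xv!r}\t{yv!r}" for s, xv, yv in
              zip(matrix.sample_ids, x.tolist(), y.tolist())]
    Path(path).write_text("\n".join(lines) + "\n")
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(x, y, s=12)
        ax.set_xlabel(probe_a)
        ax.set_ylabel(probe_b)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
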