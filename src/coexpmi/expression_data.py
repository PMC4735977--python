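"""Expression-matrix data model, TSV/CSV I/O and synthetic data generation.

The central container is :class:`ExpressionMatrix`: a probes-by-samples
matrix of nonnegative signal intensities (the already-summarised output of a
microarray pipeline), with unique probe and sample identifiers and an
optional cell-type label.  Companion tables are a probe-to-gene-symbol
annotation and a present/absent/marginal detection-call matrix of the same
shape.

The synthetic generators emulate expression-profile pairs with controllable
dependency structure — linear, monotone nonlinear, rank-block-permuted
(strong dependency with vanishing linear correlation), and independent —
and whole cohorts with an optional shared latent factor, so every
correlation statistic in the package can be exercised without any real
array data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DuplicateIdError,
    EmptyMatrixError,
    InvalidValueError,
    LengthMismatchError,
    MatrixParseError,
    UnknownProbeError,
)

__all__ = [
    "ExpressionMatrix",
    "ProbeAnnotation",
    "DetectionCallMatrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_probe_annotation",
    "read_call_matrix",
    "simulate_pair",
    "simulate_matrix",
    "PAIR_KINDS",
]

_SEPARATORS = {"tsv": "\t", "csv": ","}

PAIR_KINDS = ("linear", "monotone_nonlinear", "permuted_dependency", "independent")


def _check_ids(ids: list[str], what: str) -> None:
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DuplicateIdError(f"duplicate {what} IDs: {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """Probes x samples matrix of nonnegative signal intensities.

    Parameters
    ----------
    probe_ids, sample_ids
        Unique identifiers for rows and columns.
    values
        Array of shape ``(len(probe_ids), len(sample_ids))``; finite,
        nonnegative.
    cell_type
        Free-text label for the cell population the samples come from.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    cell_type: str = ""

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidValueError("values must be a 2-D array")
        if len(self.probe_ids) == 0 or len(self.sample_ids) == 0:
            raise EmptyMatrixError("matrix must have at least one probe and one sample")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise InvalidValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        _check_ids(self.probe_ids, "probe")
        _check_ids(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            raise InvalidValueError("expression values must be finite (no NaN/inf)")
        if np.any(self.values < 0):
            raise InvalidValueError("expression values must be nonnegative")
        self._row = {p: i for i, p in enumerate(self.probe_ids)}

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def vector(self, probe_id: str) -> np.ndarray:
        """Expression vector of one probe across samples (a view)."""
        try:
            return self.values[self._row[probe_id]]
        except KeyError:
            raise UnknownProbeError(f"unknown probe ID {probe_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.probe_ids, name="probe_id"),
            columns=self.sample_ids,
        )


@dataclass
class ProbeAnnotation:
    """Mapping probe_id -> gene symbol (many probes may share a symbol)."""

    symbols: dict[str, str]

    def __post_init__(self) -> None:
        for probe, sym in self.symbols.items():
            if not str(sym).strip():
                raise InvalidValueError(f"empty gene symbol for probe {probe!r}")
        self.symbols = {str(p): str(s) for p, s in self.symbols.items()}

    def symbol(self, probe_id: str, default: str | None = None) -> str:
        if probe_id in self.symbols:
            return self.symbols[probe_id]
        if default is not None:
            return default
        raise UnknownProbeError(f"no gene symbol for probe {probe_id!r}")


_CALL_CODES = frozenset("PAM")


@dataclass
class DetectionCallMatrix:
    """Present/absent/marginal calls; same shape and IDs as a companion matrix.

    Entries are the single characters ``P``, ``A`` and ``M``, mirroring the
    usual detection-call convention of array summarisation software.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    calls: np.ndarray  # dtype '<U1'

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.calls = np.asarray(self.calls, dtype="<U1")
        if self.calls.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise InvalidValueError("call-matrix shape does not match its IDs")
        _check_ids(self.probe_ids, "probe")
        _check_ids(self.sample_ids, "sample")
        bad = set(np.unique(self.calls)) - _CALL_CODES
        if bad:
            raise InvalidValueError(f"detection calls must be P/A/M, got {sorted(bad)}")
        self._row = {p: i for i, p in enumerate(self.probe_ids)}

    def vector(self, probe_id: str) -> np.ndarray:
        try:
            return self.calls[self._row[probe_id]]
        except KeyError:
            raise UnknownProbeError(f"unknown probe ID {probe_id!r}") from None

    def check_companion(self, matrix: ExpressionMatrix) -> None:
        if self.probe_ids != matrix.probe_ids or self.sample_ids != matrix.sample_ids:
            raise LengthMismatchError(
                "detection-call matrix IDs do not match the expression matrix"
            )


def read_expression_matrix(path, dialect: str = "tsv",
                           cell_type: str = "") -> ExpressionMatrix:
    """Read a probes-x-samples matrix from TSV (default) or CSV.

    Layout: a mandatory header row of sample IDs; first column probe IDs.
    Non-numeric, missing or negative cells are rejected (the upstream
    pipeline leaves none after preprocessing), with a distinct error per
    failure mode.
    """
    sep = _sep(dialect)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0,
                         float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as e:
        raise MatrixParseError(f"cannot parse {path}: {e}") from e
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise EmptyMatrixError(f"{path} holds an empty matrix")
    probe_ids = [str(p) for p in df.index]
    sample_ids = [str(s) for s in df.columns]
    _check_ids(probe_ids, "probe")
    _check_ids(sample_ids, "sample")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as e:
        raise InvalidValueError(f"non-numeric cell in {path}: {e}") from e
    if np.isnan(values).any():
        raise InvalidValueError(f"missing values in {path} are not accepted")
    return ExpressionMatrix(probe_ids, sample_ids, values, cell_type=cell_type)


def write_expression_matrix(matrix: ExpressionMatrix, path, dialect: str = "tsv") -> None:
    """Write a matrix so that :func:`read_expression_matrix` inverts it.

    Values are printed with the shortest decimal representation that
    round-trips the underlying float, so read-after-write is bit-exact.
    """
    sep = _sep(dialect)
    df = matrix.to_frame()
    df.to_csv(path, sep=sep)


def matrix_to_text(matrix: ExpressionMatrix, dialect: str = "tsv") -> str:
    buf = io.StringIO()
    matrix.to_frame().to_csv(buf, sep=_sep(dialect))
    return buf.getvalue()


def read_probe_annotation(path, dialect: str = "tsv") -> ProbeAnnotation:
    """Read a two-column (probe_id, gene_symbol) table with header row."""
    try:
        df = pd.read_csv(path, sep=_sep(dialect), header=0, dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise MatrixParseError(f"cannot parse annotation {path}: {e}") from e
    if df.shape[1] < 2:
        raise MatrixParseError(f"annotation {path} needs two columns")
    probes = df.iloc[:, 0].tolist()
    _check_ids(probes, "probe")
    return ProbeAnnotation(dict(zip(probes, df.iloc[:, 1].tolist())))


def read_call_matrix(path, dialect: str = "tsv",
                     companion: ExpressionMatrix | None = None) -> DetectionCallMatrix:
    """Read a P/A/M detection-call matrix; optionally check a companion."""
    try:
        df = pd.read_csv(path, sep=_sep(dialect), index_col=0, header=0, dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise MatrixParseError(f"cannot parse call matrix {path}: {e}") from e
    calls = DetectionCallMatrix(
        [str(p) for p in df.index], [str(s) for s in df.columns], df.to_numpy()
    )
    if companion is not None:
        calls.check_companion(companion)
    return calls


def _sep(dialect: str) -> str:
    try:
        return _SEPARATORS[dialect]
    except KeyError:
        raise MatrixParseError(
            f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'"
        ) from None


# ---------------------------------------------------------------------------
# synthetic data
# ---------------------------------------------------------------------------

#: Default observation noise (standard deviation) added to dependent pair
#: generators, on the unit dynamic range of the generated profiles.  Roughly
#: the residual scatter of replicate normalised array measurements.
DEFAULT_NOISE_SD = 0.05

#: Number of rank blocks used by the permuted-dependency generator; matches
#: the default adaptive bin count so that the planted dependency is fully
#: visible at that discretisation resolution.
_PERMUTATION_BLOCKS = 11


def _near_zero_permutation(m: int, rng: np.random.Generator, trials: int = 300) -> np.ndarray:
    """A permutation of range(m) whose linear correlation with the identity
    is as close to zero as a short seeded search finds."""
    idx = np.arange(m, dtype=float)
    idx = idx - idx.mean()
    best, best_c = None, np.inf
    for _ in range(trials):
        perm = rng.permutation(m)
        c = abs(float(np.dot(idx, perm - perm.mean())))
        if c < best_c:
            best, best_c = perm, c
            if c == 0.0:
                break
    return best


def simulate_pair(kind: str, n: int, noise_sd: float = DEFAULT_NOISE_SD,
                  seed: int | np.random.Generator = 0) -> tuple[np.ndarray, np.ndarray]:
    """Generate one reproducible pair of expression vectors.

    Kinds
    -----
    ``linear``
        ``y = a*x + noise`` with positive slope; the textbook case a Pearson
        coefficient detects.
    ``monotone_nonlinear``
        ``y = x**3 + noise``: monotone but curved, so equal-frequency
        discretisation sees the full dependency while r underestimates it.
    ``permuted_dependency``
        y is a deterministic bijection of x's rank that destroys the linear
        trend: ranks are grouped into ``min(n, 11)`` equal blocks and the
        blocks are permuted by a seeded permutation with near-zero linear
        correlation (within-block order preserved).  The result has r near 0
        but maximal mutual information at the matching bin resolution.
    ``independent``
        x and y drawn independently.

    All values are nonnegative; ``noise_sd`` is the SD of additive Gaussian
    noise (clipped at zero).  Equal seeds give identical vectors.
    """
    if kind not in PAIR_KINDS:
        raise InvalidValueError(f"unknown pair kind {kind!r}; expected one of {PAIR_KINDS}")
    if n < 5:
        raise InvalidValueError(f"need n >= 5 samples, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if kind == "independent":
        return rng.uniform(0.0, 1.0, n), rng.uniform(0.0, 1.0, n)

    # Noisy dependent profiles stay nonnegative by reflecting at zero
    # (|y|): unlike clipping, reflection leaves no tied mass at 0, which
    # would defeat equal-frequency binning.
    if kind == "linear":
        x = rng.uniform(0.0, 1.0, n)
        y = 0.9 * x + rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.9 * x
        return x, np.abs(y)

    if kind == "monotone_nonlinear":
        x = rng.uniform(0.0, 1.0, n)
        y = x ** 3 + (rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0)
        return x, np.abs(y)

    # permuted_dependency: equally spaced x, block-permuted copy as y
    x = (2 * np.arange(n) + 1) / (2 * n)
    n_blocks = min(n, _PERMUTATION_BLOCKS)
    # block b covers sorted ranks [ceil(b*n/B), ceil((b+1)*n/B))
    edges = np.ceil(np.arange(n_blocks + 1) * n / n_blocks).astype(int)
    perm = _near_zero_permutation(n_blocks, rng)
    y = np.empty(n)
    for b in range(n_blocks):
        lo, hi = edges[b], edges[b + 1]
        src_lo, src_hi = edges[perm[b]], edges[perm[b] + 1]
        width = hi - lo
        # map within-block order onto the target block's values
        take = np.linspace(src_lo, src_hi - 1, width).round().astype(int)
        y[lo:hi] = x[take]
    if noise_sd > 0:
        y = np.abs(y + rng.normal(0.0, noise_sd, n))
    order = rng.permutation(n)  # shuffle sample order; dependency is pairwise
    return x[order], y[order]


def simulate_matrix(n_probes: int, n_samples: int, *, kind: str = "independent",
                    planted: tuple[str, ...] = (), noise_sd: float = DEFAULT_NOISE_SD,
                    seed: int = 0, cell_type: str = "synthetic") -> ExpressionMatrix:
    """Generate a whole probes-x-samples matrix.

    ``kind`` sets the background:

    - ``independent``: every probe an independent log-normal intensity profile;
    - ``latent_factor``: probes load (with random positive loadings) on one
      shared per-sample factor, so most probe pairs are genuinely dependent —
      the typical situation in a real expression compendium;
    - a pair kind from :data:`PAIR_KINDS`: consecutive probe rows form
      independent pairs with that dependency (``n_probes`` must be even).

    ``planted`` appends, after the background probes, one extra pair per
    listed kind with predictable IDs ``planted{i}_{kind}_a`` / ``_b``.
    """
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    ids: list[str] = []

    if kind == "independent":
        for i in range(n_probes):
            rows.append(rng.lognormal(mean=5.0, sigma=1.0, size=n_samples))
            ids.append(f"probe_{i:04d}")
    elif kind == "latent_factor":
        z = rng.normal(size=n_samples)
        for i in range(n_probes):
            loading = rng.uniform(0.6, 1.2)
            rows.append(np.exp(loading * z + 0.5 * rng.normal(size=n_samples)))
            ids.append(f"probe_{i:04d}")
    elif kind in PAIR_KINDS:
        if n_probes % 2:
            raise InvalidValueError(f"kind={kind!r} pairs probes; n_probes must be even")
        for i in range(n_probes // 2):
            x, y = simulate_pair(kind, n_samples, noise_sd=noise_sd, seed=rng)
            rows.extend([x, y])
            ids.extend([f"pair{i:03d}_a", f"pair{i:03d}_b"])
    else:
        raise InvalidValueError(f"unknown matrix kind {kind!r}")

    for i, pk in enumerate(planted):
        x, y = simulate_pair(pk, n_samples, noise_sd=noise_sd, seed=rng)
        rows.extend([x, y])
        ids.extend([f"planted{i}_{pk}_a", f"planted{i}_{pk}_b"])

    samples = [f"sample_{j:04d}" for j in range(n_samples)]
    return ExpressionMatrix(ids, samples, np.vstack(rows), cell_type=cell_type)
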