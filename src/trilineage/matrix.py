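"""Expression matrices, cluster assignments and the file formats that carry them.

The central container is :class:`ExpressionMatrix`: a dense genes x samples
matrix of log2 expression values addressed by gene and sample identifiers.
Genes are always rows and are always addressed by id, never by positional
index.  Cluster assignments map sample ids to cluster labels and are kept
separate from the matrix so the same matrix can be re-clustered repeatedly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ClusterAssignment",
    "FormatError",
    "ValidationError",
    "load_expression_matrix",
    "write_expression_matrix",
    "load_geo_series_matrix",
    "load_gene_list",
    "load_cluster_assignment",
    "write_cluster_assignment",
    "restrict_to_genes",
    "log2_transform",
    "normalize_percentile",
]


class FormatError(ValueError):
    """A file could not be parsed as the expected format."""


class ValidationError(ValueError):
    """Parsed data violate an invariant (duplicate ids, shape mismatch, ...)."""


@dataclass
class ExpressionMatrix:
    """Dense genes x samples expression matrix in log2 units.

    Parameters
    ----------
    gene_ids
        Unique row identifiers (gene symbols).
    sample_ids
        Unique column identifiers.
    values
        Real matrix of shape ``(len(gene_ids), len(sample_ids))``.
    cluster_of
        Optional map from sample id to cluster label.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    cluster_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes[:10]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValidationError(f"duplicate sample ids: {dupes[:10]}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.cluster_of is not None:
            unknown = set(self.cluster_of) - set(self.sample_ids)
            if unknown:
                raise ValidationError(f"cluster labels for unknown samples: {sorted(unknown)[:10]}")

    # -- indexed access -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._gene_pos[gene_id]
        except AttributeError:
            self._gene_pos = {g: i for i, g in enumerate(self.gene_ids)}
            return self._gene_pos[gene_id]

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index(gene_id)]

    def columns_for(self, sample_ids: list[str]) -> np.ndarray:
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        return self.values[:, [pos[s] for s in sample_ids]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, cluster_of: dict[str, str] | None = None) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
            cluster_of=cluster_of,
        )

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class ClusterAssignment:
    """Map from sample id to cluster label; every sample has exactly one label."""

    labels: dict[str, str]
    _members: dict[str, list[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.labels = {str(k): str(v) for k, v in self.labels.items()}
        members: dict[str, list[str]] = {}
        for sample, lab in self.labels.items():
            members.setdefault(lab, []).append(sample)
        self._members = members

    @property
    def clusters(self) -> dict[str, int]:
        """Cluster label -> member count."""
        return {lab: len(m) for lab, m in self._members.items()}

    def members(self, label: str) -> list[str]:
        if label not in self._members:
            raise KeyError(f"no cluster labelled {label!r}")
        return list(self._members[label])

    def __len__(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def load_expression_matrix(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a genes x samples table: first row sample ids, first column gene ids."""
    try:
        frame = pd.read_csv(path, sep=delimiter, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: could not parse as delimited table: {exc}") from exc
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise FormatError(f"{path}: table has no data rows or columns")
    non_numeric = [c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)]
    if non_numeric:
        for col in non_numeric:
            bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()]
            if len(bad):
                raise FormatError(
                    f"{path}: non-numeric value {bad.iloc[0]!r} in column {col!r}, "
                    f"row {bad.index[0]!r}"
                )
        frame = frame.astype(float)
    return ExpressionMatrix.from_frame(frame)


def write_expression_matrix(m: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    m.to_frame().to_csv(path, sep=delimiter, float_format="%.17g")


def load_geo_series_matrix(path) -> ExpressionMatrix:
    """Read the table block of a GEO series-matrix text file.

    Only the rows between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` are parsed; no network access is involved.
    """
    lines = []
    inside = False
    with open(path) as handle:
        for line in handle:
            stripped = line.strip()
            if stripped == "!series_matrix_table_begin":
                inside = True
                continue
            if stripped == "!series_matrix_table_end":
                inside = False
                break
            if inside:
                lines.append(line)
    if not lines:
        raise FormatError(f"{path}: no series_matrix table block found")
    from io import StringIO

    frame = pd.read_csv(StringIO("".join(lines)), sep="\t", index_col=0)
    frame.index = [str(g).strip('"') for g in frame.index]
    frame.columns = [str(s).strip('"') for s in frame.columns]
    return ExpressionMatrix.from_frame(frame)


def load_gene_list(path) -> list[str]:
    """One gene symbol per line; ``#`` starts a comment; blank lines ignored."""
    genes: list[str] = []
    with open(path) as handle:
        for line in handle:
            entry = line.split("#", 1)[0].strip()
            if entry:
                genes.append(entry)
    return genes


def load_cluster_assignment(path) -> ClusterAssignment:
    """Two-column TSV (sample_id, cluster_label) with a header row."""
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: expected two tab-separated columns, got {frame.shape[1]}")
    sample_col, label_col = frame.columns[:2]
    if frame[sample_col].duplicated().any():
        dupes = frame[sample_col][frame[sample_col].duplicated()].tolist()
        raise ValidationError(f"{path}: samples assigned more than once: {dupes[:10]}")
    return ClusterAssignment(dict(zip(frame[sample_col], frame[label_col])))


def write_cluster_assignment(assignment: ClusterAssignment, path) -> None:
    frame = pd.DataFrame(
        {"sample_id": list(assignment.labels), "cluster_label": list(assignment.labels.values())}
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# preprocessing transforms
# ---------------------------------------------------------------------------

def restrict_to_genes(m: ExpressionMatrix, whitelist: list[str]) -> ExpressionMatrix:
    """Keep only whitelisted genes, in the matrix's original row order.

    Whitelist entries absent from the matrix are counted and logged; an empty
    intersection is an error.
    """
    wanted = set(whitelist)
    keep = [i for i, g in enumerate(m.gene_ids) if g in wanted]
    if not keep:
        raise ValidationError("gene whitelist is disjoint from the matrix gene ids")
    missing = wanted - set(m.gene_ids)
    if missing:
        logger.warning(
            "restrict_to_genes: %d whitelist entries absent from matrix (e.g. %s)",
            len(missing),
            sorted(missing)[:5],
        )
    return ExpressionMatrix(
        gene_ids=[m.gene_ids[i] for i in keep],
        sample_ids=list(m.sample_ids),
        values=m.values[keep],
        cluster_of=dict(m.cluster_of) if m.cluster_of else None,
    )


def log2_transform(m: ExpressionMatrix, pseudocount: float = 0.0) -> ExpressionMatrix:
    """Replace values by ``log2(value + pseudocount)``.

    Microarray intensities are transformed with pseudocount 0; single-cell
    expression values use pseudocount 1 so zeros map to 0.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    shifted = m.values + pseudocount
    if np.any(shifted <= 0):
        rows, cols = np.nonzero(shifted <= 0)
        offenders = [
            (m.gene_ids[i], m.sample_ids[j], m.values[i, j]) for i, j in zip(rows[:10], cols[:10])
        ]
        raise ValueError(
            f"log2 undefined for {len(rows)} nonpositive entries "
            f"(value + pseudocount <= 0), e.g. {offenders}"
        )
    return m.with_values(np.log2(shifted))


def normalize_percentile(m: ExpressionMatrix, q: float = 90.0) -> ExpressionMatrix:
    """Divide each gene row by its own q-th percentile value.

    Genes whose q-th percentile is zero (or negative) cannot be scaled and are
    dropped with a log message.
    """
    if not 0 < q <= 100:
        raise ValueError("q must be in (0, 100]")
    scale = np.percentile(m.values, q, axis=1)
    keep = np.nonzero(scale > 0)[0]
    dropped = [m.gene_ids[i] for i in np.nonzero(scale <= 0)[0]]
    if dropped:
        logger.warning(
            "normalize_percentile: dropped %d genes with nonpositive %gth percentile (e.g. %s)",
            len(dropped),
            q,
            dropped[:5],
        )
    if keep.size == 0:
        raise ValidationError("all genes dropped: every row has nonpositive percentile")
    return ExpressionMatrix(
        gene_ids=[m.gene_ids[i] for i in keep],
        sample_ids=list(m.sample_ids),
        values=m.values[keep] / scale[keep, None],
        cluster_of=dict(m.cluster_of) if m.cluster_of else None,
    )
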