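"""Expression-matrix normalisation, differential expression and gene sets.

The differential-expression routine is a deliberately simple, fully
specified stand-in for moderated linear models: a per-gene two-sample
t-test on log2 values whose pooled variance is shrunk toward the mean
variance across genes with a FIXED prior weight (``PRIOR_DF`` pseudo
degrees of freedom), and whose null distribution is Student t with
``residual df + PRIOR_DF``.  This mimics the variance-stabilising effect
of empirical-Bayes moderation at small replicate numbers but estimates
nothing from the data beyond the mean variance; it is NOT an
empirical-Bayes reimplementation, and results will differ from moderated-t
pipelines on real data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from cistra.enrichment import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "DEResult",
    "GeneSet",
    "OverlapSummary",
    "quantile_normalize",
    "differential_expression",
    "core_regulated_set",
    "set_overlap_summary",
    "signature_projection",
    "read_expression_tsv",
    "read_groups_tsv",
    "read_gene_set",
    "write_gene_set",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 intensities with sample group labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        unknown = set(self.groups) - set(self.sample_ids)
        if unknown:
            raise ValueError(f"group labels for unknown samples: {sorted(unknown)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def samples_in_group(self, label: str) -> list[int]:
        return [
            i for i, s in enumerate(self.sample_ids) if self.groups.get(s) == label
        ]


@dataclass
class DEResult:
    """Per-gene differential-expression outcome for one contrast."""

    gene_id: str
    log_fc: float  # mean(group_b) - mean(group_a), log2 units
    p: float
    adj_p: float
    direction: Literal["up", "down", "ns"]

    def __post_init__(self) -> None:
        if self.adj_p < self.p - 1e-12:
            raise ValueError("adjusted p cannot be smaller than raw p")


@dataclass
class GeneSet:
    name: str
    gene_ids: frozenset[str]
    provenance: str = ""

    def __init__(self, name: str, gene_ids: Iterable[str], provenance: str = ""):
        self.name = name
        self.gene_ids = frozenset(gene_ids)
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class OverlapSummary:
    n_a: int
    n_b: int
    n_overlap: int
    pct_overlap: float  # raw, over the smaller set
    pct_rounded: int
    pct_of_a: float
    pct_of_b: float


# ---------------------------------------------------------------------------
# Normalisation


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile normalisation across samples.

    Each column's sorted values are replaced by the cross-column mean of
    sorted values; tied entries within a column receive the mean of the
    candidate values for their tied ranks.  Idempotent; all column
    distributions are identical afterwards.
    """
    v = m.values
    if v.shape[1] < 2:
        raise ValueError("need >= 2 samples to quantile normalize")
    sorted_cols = np.sort(v, axis=0)
    ref = sorted_cols.mean(axis=1)  # target distribution
    out = np.empty_like(v)
    for j in range(v.shape[1]):
        col = v[:, j]
        order = np.argsort(col, kind="stable")
        ranks = np.empty(col.size, dtype=np.int64)
        ranks[order] = np.arange(col.size)
        assigned = ref[ranks]
        # average candidate values over tied entries
        uniq, inv = np.unique(col, return_inverse=True)
        if uniq.size < col.size:
            sums = np.bincount(inv, weights=assigned)
            cnts = np.bincount(inv)
            assigned = (sums / cnts)[inv]
        out[:, j] = assigned
    return ExpressionMatrix(
        list(m.gene_ids), list(m.sample_ids), out, dict(m.groups)
    )


# ---------------------------------------------------------------------------
# Differential expression

#: Fixed prior pseudo-df of the variance-shrinkage stand-in.
PRIOR_DF = 8.0


def differential_expression(
    m: ExpressionMatrix,
    group_a: str,
    group_b: str,
    threshold: float = 0.05,
) -> list[DEResult]:
    """Moderated two-sample t-test of ``group_b`` vs ``group_a`` per gene.

    The pooled per-gene variance ``s2`` (residual df ``d = na + nb - 2``) is
    shrunk toward the across-gene mean variance ``s2_bar``::

        s2_tilde = (PRIOR_DF * s2_bar + d * s2) / (PRIOR_DF + d)

    and the statistic referred to Student t with ``d + PRIOR_DF`` degrees of
    freedom; BH adjustment across genes.  ``log_fc`` is mean(group_b) -
    mean(group_a): with ``group_a`` the control, positive means up in the
    condition.
    """
    ia = m.samples_in_group(group_a)
    ib = m.samples_in_group(group_b)
    for label, idx in ((group_a, ia), (group_b, ib)):
        if label not in set(m.groups.values()):
            raise ValueError(f"unknown group label {label!r}")
        if len(idx) < 2:
            raise ValueError(f"group {label!r} has {len(idx)} sample(s); need >= 2")
    xa, xb = m.values[:, ia], m.values[:, ib]
    na, nb = xa.shape[1], xb.shape[1]
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    d = na + nb - 2
    s2 = ((na - 1) * xa.var(axis=1, ddof=1) + (nb - 1) * xb.var(axis=1, ddof=1)) / d
    s2_tilde = (PRIOR_DF * s2.mean() + d * s2) / (PRIOR_DF + d)
    denom = np.sqrt(s2_tilde * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_b - mean_a) / denom
    t = np.where(denom == 0, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), d + PRIOR_DF)
    adj = bh_fdr(p)
    log_fc = mean_b - mean_a
    results = []
    for i, g in enumerate(m.gene_ids):
        if adj[i] < threshold and log_fc[i] > 0:
            direction = "up"
        elif adj[i] < threshold and log_fc[i] < 0:
            direction = "down"
        else:
            direction = "ns"
        results.append(
            DEResult(g, float(log_fc[i]), float(p[i]), float(adj[i]), direction)
        )
    return results


def core_regulated_set(
    de_oe: Sequence[DEResult],
    de_kd: Sequence[DEResult],
    threshold: float = 0.05,
    name: str = "core_regulated",
) -> GeneSet:
    """Genes significantly up in the OE contrast AND down in the KD contrast
    (both condition-vs-control, BH-adjusted p below ``threshold``)."""
    genes_oe = {r.gene_id for r in de_oe}
    genes_kd = {r.gene_id for r in de_kd}
    if genes_oe != genes_kd:
        diff = len(genes_oe.symmetric_difference(genes_kd))
        raise ValueError(
            f"DE lists cover different gene universes (symmetric difference "
            f"of {diff} genes)"
        )
    up_oe = {r.gene_id for r in de_oe if r.adj_p < threshold and r.log_fc > 0}
    down_kd = {r.gene_id for r in de_kd if r.adj_p < threshold and r.log_fc < 0}
    core = up_oe & down_kd
    if not core:
        logger.warning("core regulated set is empty at threshold %g", threshold)
    return GeneSet(
        name,
        core,
        provenance=f"OE-up AND KD-down at adjusted p < {threshold}",
    )


def set_overlap_summary(a: GeneSet, b: GeneSet) -> OverlapSummary:
    """Overlap of two gene sets; the headline percentage uses the smaller
    set as denominator (both per-set ratios are retained)."""
    if len(a) == 0 and len(b) == 0:
        raise ValueError("both gene sets are empty")
    n_overlap = len(a.gene_ids & b.gene_ids)
    smaller = min(len(a), len(b))
    pct = 100.0 * n_overlap / smaller if smaller else 0.0
    return OverlapSummary(
        n_a=len(a),
        n_b=len(b),
        n_overlap=n_overlap,
        pct_overlap=pct,
        pct_rounded=int(round(pct)),
        pct_of_a=100.0 * n_overlap / len(a) if len(a) else float("nan"),
        pct_of_b=100.0 * n_overlap / len(b) if len(b) else float("nan"),
    )


# ---------------------------------------------------------------------------
# Signature projection


def signature_projection(
    m: ExpressionMatrix,
    sig: GeneSet,
    k: int,
    true_labels: Mapping[str, str] | None = None,
) -> tuple[list[str], dict[str, int], float | None]:
    """Cluster samples on the signature genes.

    Restricts to signature genes present in the matrix, row-standardises,
    clusters samples by average linkage on 1 - Pearson correlation and cuts
    the tree into ``k`` clusters.  Returns (sample order by cluster, sample
    -> cluster label, adjusted Rand index vs ``true_labels`` or None).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    present = [g for g in m.gene_ids if g in sig.gene_ids]
    missing = len(sig) - len(present)
    if missing:
        logger.warning(
            "%d of %d signature genes absent from the matrix", missing, len(sig)
        )
    if len(present) < 2:
        raise ValueError("fewer than 2 signature genes present in the matrix")
    idx = [m.gene_ids.index(g) for g in present]
    sub = m.values[idx, :]
    sd = sub.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    n_samples = len(m.sample_ids)
    if k > n_samples:
        raise ValueError("k cannot exceed the number of samples")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(z.T)
    dist = 1.0 - corr
    dist[np.isnan(dist)] = 1.0
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(np.clip((dist + dist.T) / 2, 0, None), checks=False),
                method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    assignment = {s: int(c) for s, c in zip(m.sample_ids, labels)}
    order = sorted(m.sample_ids, key=lambda s: (assignment[s], s))
    ari = None
    if true_labels is not None:
        truth = [true_labels[s] for s in m.sample_ids]
        ari = float(adjusted_rand_score(truth, labels))
    return order, assignment, ari


# ---------------------------------------------------------------------------
# I/O


def read_expression_tsv(
    matrix_path: str | Path, groups_path: str | Path | None = None
) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids)
    plus an optional two-column sample-to-group TSV."""
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    groups = read_groups_tsv(groups_path) if groups_path else {}
    return ExpressionMatrix(
        [str(g) for g in df.index],
        [str(s) for s in df.columns],
        df.to_numpy(dtype=float),
        groups,
    )


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError("groups file needs sample_id and group columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_expression_tsv(
    m: ExpressionMatrix, matrix_path: str | Path, groups_path: str | Path | None = None
) -> None:
    m.to_frame().to_csv(matrix_path, sep="\t", index_label="gene_id")
    if groups_path is not None:
        pd.DataFrame(
            {"sample_id": list(m.groups), "group": list(m.groups.values())}
        ).to_csv(groups_path, sep="\t", index=False)


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """One gene id per line; ``#`` comment lines carry provenance."""
    path = Path(path)
    ids, provenance = [], []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            provenance.append(line.lstrip("# "))
        else:
            ids.append(line)
    return GeneSet(name or path.stem, ids, "; ".join(provenance))


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        if gs.provenance:
            fh.write(f"# {gs.provenance}\n")
        for g in sorted(gs.gene_ids):
            fh.write(g + "\n")
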