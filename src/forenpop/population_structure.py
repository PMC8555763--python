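"""Assignment informativeness, PCA and classical MDS.

Rosenberg's informativeness for assignment I_n measures, in nats, how
much a locus's allele frequencies tell about which of K groups an
allele was drawn from; it is 0 when all groups share frequencies and at
most ln K. PCA here is plain SVD of the column-centered input (allele
frequencies for population-level analysis; minor-allele dosages for
individual-level analysis). Classical (Torgerson) MDS embeds a
dissimilarity matrix through double-centering of squared distances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    AlleleFrequencyTable,
    DistanceMatrix,
    GenotypeTable,
    ValidationError,
)


def _xlogx(p: float) -> float:
    return 0.0 if p <= 0.0 else p * math.log(p)


def informativeness_in(group_freqs: list[dict]) -> float:
    """Rosenberg's I_n for one locus over K groups.

    ``group_freqs``: one {allele: frequency} map per group; allele sets
    are unioned with zero fill. With p̄_j the unweighted mean frequency
    of allele j: I_n = Σ_j (−p̄_j ln p̄_j + Σ_i (p_ij/K) ln p_ij),
    convention 0·ln 0 = 0.
    """
    if len(group_freqs) < 2:
        raise ValidationError("I_n needs >= 2 groups")
    alleles = sorted(set().union(*group_freqs))
    K = len(group_freqs)
    total = 0.0
    for a in alleles:
        p = [g.get(a, 0.0) for g in group_freqs]
        p_bar = sum(p) / K
        total += -_xlogx(p_bar) + sum(_xlogx(pi) for pi in p) / K
    return max(total, 0.0)


def one_vs_rest_in(
    group_freqs: dict, target: str, group_sizes: dict
) -> float:
    """I_n of a 2-way contrast: one group against the pooled rest.

    ``group_freqs``: group label → {allele: frequency}; ``group_sizes``:
    group label → chromosome count, used to weight the pooled
    complement so its frequencies are those of the merged sample.
    """
    if target not in group_freqs:
        raise ValidationError(f"target group {target!r} not present")
    rest = [g for g in group_freqs if g != target]
    if not rest:
        raise ValidationError("need at least one non-target group")
    weights = np.array([group_sizes[g] for g in rest], dtype=float)
    weights /= weights.sum()
    alleles = sorted(set().union(*group_freqs.values()))
    pooled = {
        a: float(sum(w * group_freqs[g].get(a, 0.0) for g, w in zip(rest, weights)))
        for a in alleles
    }
    return informativeness_in([dict(group_freqs[target]), pooled])


def in_table(
    freqs: AlleleFrequencyTable, contrasts: str = "both"
) -> pd.DataFrame:
    """I_n per locus: the all-groups contrast and/or one-vs-rest rows.

    Returns columns locus, contrast, In; contrast is "all" or
    "vs_rest:<group>".
    """
    if contrasts not in ("all", "one_vs_rest", "both"):
        raise ValueError(f"unknown contrasts mode {contrasts!r}")
    pops = freqs.populations
    rows = []
    for locus in freqs.loci:
        per_pop = {p: freqs.freqs(p, locus) for p in pops}
        per_pop = {p: f for p, f in per_pop.items() if f}
        if len(per_pop) < 2:
            continue
        sizes = {p: freqs.n(p, locus) for p in per_pop}
        if contrasts in ("all", "both"):
            rows.append(
                {
                    "locus": locus,
                    "contrast": "all",
                    "In": informativeness_in(list(per_pop.values())),
                }
            )
        if contrasts in ("one_vs_rest", "both") and len(per_pop) >= 2:
            for p in per_pop:
                rows.append(
                    {
                        "locus": locus,
                        "contrast": f"vs_rest:{p}",
                        "In": one_vs_rest_in(per_pop, p, sizes),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    """Low-dimensional coordinates with explained-variance fractions."""

    labels: list[str]
    coordinates: np.ndarray  # entities × components
    explained: np.ndarray  # fraction of variance per component

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.explained = np.asarray(self.explained, dtype=float)
        if np.any(np.diff(self.explained) > 1e-12):
            raise ValidationError("explained fractions must be non-increasing")
        if self.explained.sum() > 1.0 + 1e-9:
            raise ValidationError("explained fractions sum above 1")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)

    def explained_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(len(self.explained))],
                "explained_fraction": self.explained,
            }
        )


def _svd_ordination(matrix: np.ndarray, labels: list[str]) -> OrdinationResult:
    """Center columns, SVD, orient each component deterministically."""
    x = matrix - matrix.mean(axis=0, keepdims=True)
    total_var = float((x**2).sum())
    if total_var == 0.0:
        k = min(x.shape)
        return OrdinationResult(
            labels=labels,
            coordinates=np.zeros((x.shape[0], k)),
            explained=np.zeros(k),
        )
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: largest-magnitude loading entry positive
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = u * s
    explained = (s**2) / total_var
    return OrdinationResult(labels=labels, coordinates=scores, explained=explained)


def pca_populations(freq_matrix) -> OrdinationResult:
    """PCA of populations on stacked allele-frequency columns.

    Accepts an AlleleFrequencyTable (converted via ``to_matrix``) or a
    populations × frequency-columns DataFrame.
    """
    if isinstance(freq_matrix, AlleleFrequencyTable):
        freq_matrix = freq_matrix.to_matrix()
    if len(freq_matrix) < 2:
        raise ValidationError("PCA needs >= 2 populations")
    return _svd_ordination(
        freq_matrix.to_numpy(dtype=float), [str(i) for i in freq_matrix.index]
    )


def dosage_matrix(
    table: GenotypeTable, loci: "list[str] | None" = None
) -> pd.DataFrame:
    """Samples × loci minor-allele dosage (0/1/2; haploid 0/1) matrix.

    Loci must be biallelic across the table; the minor allele is the
    globally rarer one (ties broken lexicographically). Missing
    genotypes become the column mean at centering time (encoded NaN
    here).
    """
    if loci is None:
        loci = [l.name for l in table.loci if l.is_snp]
    cols = {}
    for locus in loci:
        tally: dict = {}
        for s in table.samples:
            cell = table.cells.get((s, locus))
            if cell is None:
                continue
            for a in cell:
                tally[a] = tally.get(a, 0) + 1
        if len(tally) > 2:
            raise ValidationError(f"locus {locus!r} is not biallelic")
        if not tally:
            continue
        minor = min(tally.items(), key=lambda kv: (kv[1], kv[0]))[0]
        col = []
        for s in table.samples:
            cell = table.cells.get((s, locus))
            col.append(
                np.nan if cell is None else float(sum(a == minor for a in cell))
            )
        cols[locus] = col
    return pd.DataFrame(cols, index=table.samples)


def pca_individuals(
    table: GenotypeTable,
    loci: "list[str] | None" = None,
    scale: bool = True,
) -> OrdinationResult:
    """Individual-level PCA on minor-allele dosages of biallelic loci.

    Columns are centered; with ``scale`` (default) also divided by their
    standard deviation. Zero-variance loci are dropped with a warning;
    missing dosages are mean-imputed (zero after centering).
    """
    dm = dosage_matrix(table, loci)
    x = dm.to_numpy(dtype=float)
    col_mean = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_mean, inds[1])
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(dm.columns, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} zero-variance loci: {dropped[:5]}...",
            stacklevel=2,
        )
    x = x[:, keep]
    if x.shape[1] == 0:
        raise ValidationError("no variable biallelic loci for PCA")
    if scale:
        x = x / x.std(axis=0)
    return _svd_ordination(x, list(table.samples))


def classical_mds(m: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Torgerson MDS of a dissimilarity matrix.

    Negative entries (e.g. negative R_st noise) are floored at 0 before
    embedding. The squared distances are double-centered; coordinates
    are the top-k eigenvectors scaled by √eigenvalue, negative
    eigenvalues being dropped (with a warning when that reduces k).
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    d = np.maximum(m.values, 0.0)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    positive = evals > 1e-12
    n_pos = int(positive.sum())
    if n_pos == 0:
        return OrdinationResult(
            labels=list(m.labels),
            coordinates=np.zeros((n, k)),
            explained=np.zeros(k),
        )
    if k > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; reducing k from {k}",
            stacklevel=2,
        )
        k = n_pos
    lam = evals[:k]
    coords = evecs[:, :k] * np.sqrt(lam)
    # deterministic orientation, as for PCA
    for i in range(coords.shape[1]):
        jmax = int(np.argmax(np.abs(coords[:, i])))
        if coords[jmax, i] < 0:
            coords[:, i] *= -1
    explained = lam / evals[positive].sum()
    return OrdinationResult(
        labels=list(m.labels), coordinates=coords, explained=explained
    )
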