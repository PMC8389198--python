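"""Shadow-price interpretation and cross-condition comparison.

Shadow prices (the duals of the metabolite mass balances, see
:mod:`redgem.optimize`) are classified by sign:

* negative — the metabolite *limits* the objective;
* zero (within tolerance) — the objective is *insensitive* to it;
* positive — the metabolite is in *surplus* for the objective.

For two or more cultivation conditions the per-metabolite shadow prices are
assembled into a metabolites x conditions matrix; a column-centred SVD
(PCA) exposes which metabolites drive the difference between the
conditions, and a simple |Δ shadow price| ranking offers the equivalent
answer for exactly two conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .optimize import FluxSolution

#: Shadow prices below this magnitude are treated as zero when classifying.
DEFAULT_ZERO_TOL = 1e-9


def classify_shadow_prices(
    solution: FluxSolution, tol: float = DEFAULT_ZERO_TOL
) -> dict[str, str]:
    """Map each metabolite to ``limiting`` / ``insensitive`` / ``surplus``.

    ``|value| <= tol`` maps to ``insensitive``; otherwise the sign decides.
    Requires an optimal solution with populated duals.
    """
    if not solution.optimal:
        raise ValueError(f"solution status is {solution.status!r}, not optimal")
    out = {}
    for met, price in solution.shadow_prices.items():
        if abs(price) <= tol:
            out[met] = "insensitive"
        elif price < 0:
            out[met] = "limiting"
        else:
            out[met] = "surplus"
    return out


@dataclass
class ShadowPriceMatrix:
    """Complete metabolites x conditions matrix of shadow prices.

    ``provenance`` records which LP produced each column (e.g. the step-1
    objective-maximisation duals of a two-step FBA).
    """

    values: pd.DataFrame  # index: metabolite ids, columns: condition names
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape[1] < 1:
            raise ValueError("need at least one condition column")
        if self.values.isna().any().any():
            holes = self.values.index[self.values.isna().any(axis=1)]
            raise ValueError(
                f"shadow-price matrix has holes for metabolites: "
                f"{list(holes)[:5]}"
            )

    @classmethod
    def from_solutions(
        cls, solutions: dict[str, FluxSolution]
    ) -> "ShadowPriceMatrix":
        """Assemble the matrix from named optimal solutions.

        Only metabolites present in every solution enter the matrix, which
        keeps it hole-free when conditions were solved on the same model.
        """
        if not solutions:
            raise ValueError("no solutions given")
        common = None
        for sol in solutions.values():
            mets = set(sol.shadow_prices)
            common = mets if common is None else common & mets
        common = sorted(common)
        data = {
            name: [sol.shadow_prices[m] for m in common]
            for name, sol in solutions.items()
        }
        values = pd.DataFrame(data, index=common)
        provenance = {
            name: f"duals of {sol.objective_id} ({sol.sense})"
            for name, sol in solutions.items()
        }
        return cls(values=values, provenance=provenance)

    def to_tsv(self, path) -> None:
        self.values.rename_axis("metabolite").to_csv(path, sep="\t")


@dataclass
class PCAResult:
    scores: pd.DataFrame  # metabolites x components
    loadings: pd.DataFrame  # conditions x components
    explained_variance_ratio: np.ndarray

    def reconstruct(self) -> np.ndarray:
        """Centered-matrix reconstruction ``scores @ loadings.T``."""
        return self.scores.to_numpy() @ self.loadings.to_numpy().T


def shadow_price_pca(matrix: ShadowPriceMatrix) -> PCAResult:
    """Column-centred SVD of the shadow-price matrix.

    Scores live on metabolites (``U Σ``), loadings on conditions (``V``).
    The sign of each component is fixed so its largest-magnitude condition
    loading is positive; explained variance ratios sum to one.  A matrix
    with no variance after centring raises ``ValueError``.
    """
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("PCA needs at least two condition columns")
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(np.abs(Xc) > 0):
        raise ValueError("shadow-price matrix has zero variance after centring")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(X.shape[1], len(s))
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(k):
        i_max = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_max] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    comp = [f"PC{j + 1}" for j in range(k)]
    var = s**2
    return PCAResult(
        scores=pd.DataFrame(U * s, index=matrix.values.index, columns=comp),
        loadings=pd.DataFrame(Vt.T, index=matrix.values.columns, columns=comp),
        explained_variance_ratio=var / var.sum(),
    )


def top_changing_metabolites(
    matrix: ShadowPriceMatrix, k: int = 70
) -> pd.DataFrame:
    """Metabolites ranked by |Δ shadow price| between two conditions.

    Descending by ``|price_B - price_A|`` with ties broken by metabolite id;
    the default ``k`` mirrors the 70-metabolite view of the study's biplot.
    ``k`` larger than the matrix returns all rows.
    """
    if matrix.values.shape[1] != 2:
        raise ValueError("ranking requires exactly two condition columns")
    a, b = matrix.values.columns
    delta = (matrix.values[b] - matrix.values[a]).abs()
    df = pd.DataFrame(
        {
            "metabolite": matrix.values.index,
            a: matrix.values[a].to_numpy(),
            b: matrix.values[b].to_numpy(),
            "abs_delta": delta.to_numpy(),
        }
    )
    df = df.sort_values(
        ["abs_delta", "metabolite"], ascending=[False, True]
    ).reset_index(drop=True)
    return df.head(min(k, len(df)))


def plot_pca_biplot(matrix: ShadowPriceMatrix, k: int = 70, ax=None):
    """Basic biplot: top-|Δ| metabolite scores plus condition loadings."""
    import matplotlib.pyplot as plt

    pca = shadow_price_pca(matrix)
    top = top_changing_metabolites(matrix, k)["metabolite"]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    pts = pca.scores.loc[top]
    ax.scatter(pts.iloc[:, 0], pts.iloc[:, 1] if pts.shape[1] > 1 else 0,
               s=12, alpha=0.7)
    scale = float(np.abs(pca.scores.to_numpy()).max() or 1.0)
    for cond in pca.loadings.index:
        x = pca.loadings.loc[cond, "PC1"] * scale
        y = pca.loadings.loc[cond, "PC2"] * scale if "PC2" in pca.loadings else 0
        ax.annotate(cond, (x, y), color="tab:blue")
        ax.arrow(0, 0, x, y, color="tab:blue", head_width=scale * 0.02)
    evr = pca.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0] * 100:.1f}%)")
    if len(evr) > 1:
        ax.set_ylabel(f"PC2 ({evr[1] * 100:.1f}%)")
    return ax
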