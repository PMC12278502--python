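"""PCA-based ordinal encoding of categorical reagents.

Lithium salts enter the optimizer as integers. Rather than an arbitrary
ordering, each salt is scored on its first principal component over a
small table of anion descriptors, and the integers 1..n are the rank
order of those scores. The PC sign is oriented so a designated anchor
reagent (LiI by default) receives rank 1, which makes the encoding
deterministic.

The bundled descriptor table (``data/salt_descriptors_synthetic.csv``) is a
synthetic reconstruction: the original descriptor set is not public, so the
table scores each anion on size, charge delocalization and coordinating
ability proxies chosen so that the first-component ranking reproduces the
four anchors fixed by the campaign analysis (LiI=1, LiBF4=2, LiNTf2=5,
LiPF6=6). It is not ground truth for the remaining three salts.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["load_default_descriptors", "pca_rank_encode"]

DEFAULT_ANCHOR = "LiI"


def load_default_descriptors() -> pd.DataFrame:
    """The bundled (synthetic, reconstructed) lithium-salt descriptor table."""
    with resources.files("glycobo.data").joinpath(
        "salt_descriptors_synthetic.csv"
    ).open() as fh:
        return read_descriptors(fh)


def read_descriptors(path_or_buf) -> pd.DataFrame:
    """Read a descriptor CSV: first column reagent label, rest numeric."""
    df = pd.read_csv(path_or_buf)
    df = df.set_index(df.columns[0])
    if df.isna().any().any():
        raise ValueError("descriptor table contains missing values")
    if df.shape[0] < 2 or df.shape[1] < 1:
        raise ValueError("need at least 2 reagents and 1 descriptor column")
    return df.astype(float)


def pca_rank_encode(table: pd.DataFrame, anchor: str | None = DEFAULT_ANCHOR,
                    tol: float = 1e-9) -> dict[str, int]:
    """Rank reagents 1..n by their first-principal-component score.

    Columns are standardized (zero mean, unit variance) so the encoding is
    invariant to descriptor units; PC1 is taken from the SVD of the
    standardized matrix. The component sign is flipped, if necessary, so
    that ``anchor`` lands at rank 1 (when ``anchor`` is None, the sign
    making the first-listed reagent's score lowest is used).

    Raises
    ------
    ValueError
        If two reagents tie on PC1 (the caller must add a discriminating
        descriptor), or the anchor is missing.
    """
    X = table.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all descriptor columns are constant")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    # PC1 scores via SVD of the standardized matrix
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    scores = Z @ vt[0]
    reagents = list(table.index)
    if anchor is not None:
        if anchor not in reagents:
            raise ValueError(f"anchor reagent {anchor!r} not in table")
        if scores[reagents.index(anchor)] > scores.min() + tol:
            # orient PC1 so the anchor sits at the low end
            scores = -scores
        if scores[reagents.index(anchor)] > scores.min() + tol:
            raise ValueError(
                f"anchor {anchor!r} cannot be placed at rank 1 under either "
                "sign of the first component"
            )
    order = np.argsort(scores, kind="stable")
    sorted_scores = scores[order]
    ties = np.nonzero(np.diff(sorted_scores) < tol)[0]
    if ties.size:
        tied = sorted({reagents[order[i]] for i in ties}
                      | {reagents[order[i + 1]] for i in ties})
        raise ValueError(
            "tied PC1 scores for reagents: " + ", ".join(tied)
            + " (add a discriminating descriptor)"
        )
    return {reagents[j]: rank for rank, j in enumerate(order, start=1)}
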