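"""FPKM normalization and the 3-standard-deviation tissue-specialization rule.

FPKM(t, i) = F(t, i) * 1e9 / (L(t) * M(i)) for fragment count F, transcript
length L in bp and per-tissue mapped-fragment total M.  A transcript is
called *specialized* in a tissue when its FPKM there exceeds its
cross-tissue mean by more than ``k`` standard deviations (sample SD,
including the candidate tissue, by default).  Per-tissue specialized counts
give a descending "transcriptional complexity" ranking of tissues.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def fpkm(counts: pd.DataFrame, lengths: pd.Series,
         totals: pd.Series | None = None) -> pd.DataFrame:
    """FPKM matrix from fragment counts (transcripts x tissues).

    ``totals`` defaults to the column sums of ``counts`` (the matrix is
    then self-contained); zero lengths or totals are rejected.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every transcript needs a positive length")
    if totals is None:
        totals = counts.sum(axis=0)
    totals = totals.reindex(counts.columns)
    if totals.isna().any() or (totals <= 0).any():
        raise ValueError("per-tissue mapped totals must be positive")
    return counts * 1e9 / np.outer(lengths, totals)


def specialized_calls(fpkm_matrix: pd.DataFrame, k: float = 3.0,
                      ddof: int = 1, exclude_self: bool = False):
    """Flag (transcript, tissue) cells with FPKM > mean + k * SD.

    Mean and SD are taken across all tissues of the transcript (the
    candidate tissue included unless ``exclude_self``); ``ddof=1`` gives
    the sample SD.  Returns ``(flags, per_tissue_counts, ranking)`` where
    ``ranking`` lists tissues by decreasing specialized-transcript count
    (the tissue-complexity ordering).
    """
    if fpkm_matrix.shape[1] < 3:
        raise ValueError("need at least 3 tissues for the SD rule")
    vals = fpkm_matrix.to_numpy(dtype=float)
    if exclude_self:
        n = vals.shape[1]
        flags = np.zeros_like(vals, dtype=bool)
        for j in range(n):
            rest = np.delete(vals, j, axis=1)
            mu = rest.mean(axis=1)
            sd = rest.std(axis=1, ddof=ddof)
            flags[:, j] = vals[:, j] > mu + k * sd
    else:
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, ddof=ddof, keepdims=True)
        flags = vals > mu + k * sd
    flags = pd.DataFrame(flags, index=fpkm_matrix.index,
                         columns=fpkm_matrix.columns)
    counts = flags.sum(axis=0).astype(int)
    ranking = counts.sort_values(ascending=False, kind="stable")
    return flags, counts, ranking


def top_expressed(fpkm_matrix: pd.DataFrame, per_tissue_n: int = 10,
                  specialized_only: bool = False, k: float = 3.0,
                  ddof: int = 1) -> dict[str, pd.DataFrame]:
    """Per tissue, the ``per_tissue_n`` highest-FPKM transcripts, optionally
    restricted to specialized calls; ties break by transcript id."""
    if specialized_only:
        flags, _, _ = specialized_calls(fpkm_matrix, k=k, ddof=ddof)
    out = {}
    for tissue in fpkm_matrix.columns:
        col = fpkm_matrix[tissue]
        if specialized_only:
            col = col[flags[tissue]]
        df = (pd.DataFrame({"transcript": col.index, "fpkm": col.to_numpy()})
              .sort_values(["fpkm", "transcript"],
                           ascending=[False, True], kind="stable")
              .head(per_tissue_n).reset_index(drop=True))
        out[tissue] = df
    return out
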