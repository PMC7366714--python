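"""Expression quantification: rpkm matrices and row-relative heatmap math.

rpkm = count * 1e9 / (library_size * feature_length).  Feature counts are
derived from total-coverage tracks as the summed per-base coverage of the
feature (mean coverage times length) — an approximation standing in for
read-level counting, which this pipeline does not perform.  Row-relative
values divide each row by its mean, so every non-zero row averages exactly 1.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import TEX_MINUS, CoverageSet


def compute_rpkm(read_counts: pd.DataFrame, feature_lengths: Dict[str, float],
                 library_sizes: Dict) -> pd.DataFrame:
    """rpkm matrix from a (features x libraries) count table.

    ``feature_lengths`` maps row index to nt; ``library_sizes`` maps column
    to total mapped reads."""
    lengths = pd.Series({f: feature_lengths[f] for f in read_counts.index},
                        dtype=float)
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be > 0")
    sizes = pd.Series({c: library_sizes[c] for c in read_counts.columns},
                      dtype=float)
    if (sizes <= 0).any():
        raise ValueError("library sizes must be > 0")
    return read_counts.astype(float).mul(1e9).div(sizes, axis=1).div(lengths, axis=0)


def row_relative(matrix: pd.DataFrame) -> Tuple[pd.DataFrame, List]:
    """Each value divided by its row mean; zero rows pass through as zeros
    and are returned in the flagged list."""
    means = matrix.mean(axis=1)
    zero = means == 0
    out = matrix.div(means.where(~zero, 1.0), axis=0)
    out[zero] = 0.0
    return out, list(matrix.index[zero])


def feature_counts_from_coverage(features: Dict[str, Tuple[int, int, str]],
                                 cov: CoverageSet,
                                 library: str = TEX_MINUS) -> pd.DataFrame:
    """Approximate read counts per feature and (condition, replicate).

    The count of a feature is the sum of per-base total coverage over its
    interval on its strand (i.e. mean coverage x length)."""
    cols = sorted({(k[0], k[1]) for k in cov.total if k[2] == library})
    data = {}
    for cond, rep in cols:
        col = {}
        for fid, (start, end, strand) in features.items():
            arr = cov.total.get((cond, rep, library, strand))
            if arr is None:
                raise KeyError(f"missing total track ({cond}, {rep}, {library}, {strand})")
            col[fid] = float(np.asarray(arr[start:end], dtype=np.int64).sum())
        data[f"{cond}:r{rep}"] = col
    return pd.DataFrame(data, index=sorted(features))


def expression_matrix(features: Dict[str, Tuple[int, int, str]],
                      cov: CoverageSet, *, condition_means: bool = True,
                      library: str = TEX_MINUS) -> pd.DataFrame:
    """rpkm matrix for feature intervals, optionally averaged per condition
    over replicates."""
    counts = feature_counts_from_coverage(features, cov, library)
    lengths = {fid: end - start for fid, (start, end, _s) in features.items()}
    sizes = {}
    for col in counts.columns:
        cond, rep = col.split(":r")
        sizes[col] = cov.library_sizes[(cond, int(rep), library)]
    rpkm = compute_rpkm(counts, lengths, sizes)
    if not condition_means:
        return rpkm
    by_cond = {}
    for col in rpkm.columns:
        cond = col.split(":r")[0]
        by_cond.setdefault(cond, []).append(col)
    return pd.DataFrame({cond: rpkm[cols].mean(axis=1)
                         for cond, cols in sorted(by_cond.items())})


def condition_ratios(matrix: pd.DataFrame) -> pd.DataFrame:
    """Raw pairwise condition rpkm ratios (non-statistical, no testing)."""
    cols = list(matrix.columns)
    out = {}
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            denom = matrix[b].replace(0, np.nan)
            out[f"{a}/{b}"] = matrix[a] / denom
    return pd.DataFrame(out)
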