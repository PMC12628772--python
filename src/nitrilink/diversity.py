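"""Repeated rarefaction, alpha diversity, and Bray-Curtis dissimilarity.

Alpha metrics follow the common ecology conventions: richness is the number
of taxa present, Shannon is in nats, and Simpson is reported as the
complement 1 - sum(p^2) (switchable; see :func:`alpha_diversity`).
"""

from __future__ import annotations

import logging
import zlib

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

log = logging.getLogger("nitrilink")


class EmptyOutputError(ValueError):
    """All samples fell below the rarefaction depth."""


def rarefy_mean(
    counts: pd.DataFrame,
    depth: int = 36103,
    reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Average of repeated rarefaction without replacement.

    Each sample with total >= ``depth`` is subsampled ``reps`` times to
    exactly ``depth`` reads (multivariate hypergeometric draws) and the
    replicate average is returned, so every retained row sums to ``depth``
    exactly.  Samples below the depth are dropped with a warning.  The seed
    stream is split per sample, so results do not depend on sample order.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    body = counts.round().astype(np.int64)
    totals = body.sum(axis=1)
    keep = totals >= depth
    dropped = list(counts.index[~keep])
    if dropped:
        log.warning(
            "dropping %d sample(s) below rarefaction depth %d: %s",
            len(dropped), depth, dropped,
        )
    if not keep.any():
        raise EmptyOutputError(
            f"all {len(counts)} samples fall below depth {depth}"
        )
    rows = {}
    for sample in counts.index:
        if not keep.loc[sample]:
            continue
        vec = body.loc[sample].to_numpy()
        if vec.sum() == depth:
            rows[sample] = vec.astype(float)  # subsample is the full vector
            continue
        # seed keyed on the sample id: independent of row order
        key = zlib.crc32(str(sample).encode())
        rng = np.random.default_rng(np.random.SeedSequence([seed, key]))
        acc = np.zeros(len(vec), dtype=float)
        for _ in range(reps):
            acc += rng.multivariate_hypergeometric(vec, depth)
        rows[sample] = acc / reps
    out = pd.DataFrame.from_dict(rows, orient="index", columns=counts.columns)
    return out.loc[[s for s in counts.index if s in rows]]


def alpha_diversity(
    counts: pd.DataFrame, simpson_form: str = "complement"
) -> pd.DataFrame:
    """Per-sample richness, Shannon entropy (nats), and Simpson index.

    ``simpson_form`` selects among ``"complement"`` (1 - sum p^2, the
    default), ``"concentration"`` (sum p^2), and ``"inverse"``
    (1 / sum p^2).  An all-zero sample yields zeros.
    """
    if simpson_form not in ("complement", "concentration", "inverse"):
        raise ValueError(f"unknown simpson_form: {simpson_form!r}")
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    totals = x.sum(axis=1)
    richness = (x > 0).sum(axis=1)
    shannon = np.zeros(len(x))
    simpson = np.zeros(len(x))
    nz = totals > 0
    p = np.zeros_like(x)
    p[nz] = x[nz] / totals[nz, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(p > 0, np.log(p), 0.0)
    shannon[nz] = -(p[nz] * logs[nz]).sum(axis=1)
    conc = (p[nz] ** 2).sum(axis=1)
    if simpson_form == "complement":
        simpson[nz] = 1.0 - conc
    elif simpson_form == "concentration":
        simpson[nz] = conc
    else:
        simpson[nz] = 1.0 / conc
    return pd.DataFrame(
        {"richness": richness, "shannon": shannon, "simpson": simpson},
        index=counts.index,
    )


def bray_curtis(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity matrix.

    BC(u, v) = sum|u - v| / sum(u + v); a pair of all-zero samples is
    defined as 0 with a warning.
    """
    if len(counts) < 2:
        raise ValueError("need at least 2 samples")
    x = counts.to_numpy(dtype=float)
    condensed = pdist(x, metric="braycurtis")
    if np.isnan(condensed).any():
        log.warning("all-zero sample pair(s); their dissimilarity is set to 0")
        condensed = np.nan_to_num(condensed, nan=0.0)
    mat = squareform(condensed)
    return pd.DataFrame(mat, index=counts.index, columns=counts.index)
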