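"""Post-processing of admixture-model outputs.

The Bayesian clustering itself is run externally; this module consumes its
tabular outputs: per-K replicate log-likelihoods LnP(D), from which the
Evanno second-difference statistic

    dK(K) = | mean L(K+1) - 2 mean L(K) + mean L(K-1) | / sd(L(K))

selects the number of clusters (endpoints are undefined; sd uses the n-1
denominator), and a lines x K membership-coefficient matrix, from which
lines are assigned to the component with the maximal coefficient when that
coefficient reaches a threshold and to "Mixed" otherwise.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ContractError, DataError, FormatError

logger = logging.getLogger(__name__)

MIXED_LABEL = "Mixed"


def read_lnpd_table(path) -> pd.DataFrame:
    """Read a TSV with columns (K, replicate, lnpd)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("K", "replicate", "lnpd"):
        if col not in df.columns:
            raise FormatError(f"LnP(D) table is missing column {col!r}")
    df["K"] = df["K"].astype(int)
    df["lnpd"] = df["lnpd"].astype(float)
    return df


def delta_k(lnpd_table: pd.DataFrame) -> pd.DataFrame:
    """Evanno dK per K from replicate log-likelihoods.

    Returns one row per K: n_replicates, mean_lnpd, sd_lnpd (n-1
    denominator, NaN with < 2 replicates) and delta_k (NaN at the grid
    endpoints and where sd is zero, with a logged note).
    """
    if "K" not in lnpd_table or "lnpd" not in lnpd_table:
        raise ContractError("LnP(D) table needs K and lnpd columns")
    g = lnpd_table.groupby("K")["lnpd"]
    out = pd.DataFrame({
        "K": sorted(lnpd_table["K"].unique()),
    }).set_index("K")
    out["n_replicates"] = g.size()
    out["mean_lnpd"] = g.mean()
    out["sd_lnpd"] = g.std(ddof=1)
    ks = out.index.to_numpy()
    if len(ks) >= 2 and not np.array_equal(ks, np.arange(ks[0], ks[-1] + 1)):
        raise DataError("K values must be contiguous")
    mean = out["mean_lnpd"].to_numpy()
    sd = out["sd_lnpd"].to_numpy()
    dk = np.full(len(ks), np.nan)
    for i in range(1, len(ks) - 1):
        if not np.isfinite(sd[i]) or sd[i] == 0:
            logger.info("dK undefined at K=%d (sd of LnP(D) is zero or undefined)", ks[i])
            continue
        dk[i] = abs(mean[i + 1] - 2.0 * mean[i] + mean[i - 1]) / sd[i]
    out["delta_k"] = dk
    return out.reset_index()


def read_membership(path) -> pd.DataFrame:
    """Read a TSV (line_id, q1..qK) into a line-indexed coefficient frame."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError("membership table needs line_id plus coefficient columns")
    df = df.set_index(df.columns[0])
    return df.astype(float)


def assign_groups(membership: pd.DataFrame, labels, threshold: float = 0.6) -> pd.Series:
    """Assign each line to its dominant component, or to "Mixed".

    A line joins the component with the maximal coefficient iff that
    coefficient is at least ``threshold``.  Component order ties go to the
    first component.  Rows must sum to 1 within 1e-6.
    """
    labels = list(labels)
    q = membership.to_numpy(dtype=float)
    if q.shape[1] != len(labels):
        raise ContractError(f"{q.shape[1]} components but {len(labels)} labels")
    if not np.allclose(q.sum(axis=1), 1.0, atol=1e-6):
        raise ContractError("membership rows must sum to 1 within 1e-6")
    best = q.argmax(axis=1)
    coef = q[np.arange(len(q)), best]
    assigned = np.where(coef >= threshold,
                        np.asarray(labels, dtype=object)[best], MIXED_LABEL)
    return pd.Series(assigned, index=membership.index, name="group")
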