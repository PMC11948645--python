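"""Graph topology: participation coefficient and its normative summaries.

The participation coefficient (PC) of a node measures how evenly its edges
spread across network modules:

    PC_i = 1 - sum_m (k_i(m) / k_i)^2

where k_i(m) is node i's degree toward module m and k_i its total degree.
PC = 0 when all edges stay within one module (maximal segregation) and
approaches 1 - 1/|M| for edges spread evenly across the |M| modules
(maximal integration). Isolated nodes are assigned PC = 0 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import NETWORKS, ParcelAtlas
from .connectome import BinaryAdjacency
from .normative import (NormativeConfig, age_effect_test, centile_scores,
                        fit_normative)
from .stats import fdr_bh

#: Column order of the PC summary table: whole brain first, then networks.
PC_FEATURES: tuple[str, ...] = ("WholeBrain",) + NETWORKS


@dataclass(frozen=True)
class PCVector:
    """Node-wise participation coefficients plus network summaries."""

    per_parcel: np.ndarray
    whole_brain: float
    per_network: dict[str, float]

    def summary(self) -> pd.Series:
        vals = {"WholeBrain": self.whole_brain, **self.per_network}
        return pd.Series([vals[f] for f in PC_FEATURES], index=list(PC_FEATURES))


def participation_coefficient(adj: BinaryAdjacency | np.ndarray,
                              atlas: ParcelAtlas) -> PCVector:
    """PC per node on a binary undirected graph with atlas modules."""
    A = adj.values if isinstance(adj, BinaryAdjacency) else np.asarray(adj, float)
    P = A.shape[0]
    if A.shape != (P, P) or not np.allclose(A, A.T):
        raise ValueError("adjacency must be square and symmetric")
    if np.any((A != 0) & (A != 1)):
        raise ValueError("adjacency must be 0/1")
    if atlas.n_parcels != P:
        raise ValueError(f"atlas covers {atlas.n_parcels} parcels, graph has {P}")
    modules = atlas.module_index()
    n_mod = len(NETWORKS)
    ind = np.zeros((P, n_mod))
    ind[np.arange(P), modules] = 1.0
    k = A.sum(axis=1)
    km = A @ ind  # degree of node i toward each module
    isolated = k == 0
    if np.any(isolated):
        warnings.warn(f"{int(isolated.sum())} isolated node(s); PC set to 0",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pc = 1.0 - np.sum((km / k[:, None]) ** 2, axis=1)
    pc[isolated] = 0.0
    labels = atlas.labels()
    per_network = {n: float(pc[labels == n].mean()) for n in NETWORKS}
    return PCVector(per_parcel=pc, whole_brain=float(pc.mean()),
                    per_network=per_network)


def pc_table(adjacencies, atlas: ParcelAtlas, index=None) -> pd.DataFrame:
    """Stack per-subject PC summaries into a subjects x features table."""
    rows = [participation_coefficient(a, atlas).summary() for a in adjacencies]
    return pd.DataFrame(rows, index=index)


def pc_centiles(pc: pd.DataFrame, age, sex, config: NormativeConfig | None = None,
                fit_mask=None) -> tuple[pd.DataFrame, dict]:
    """Centile scores for each PC summary (whole brain + 7 networks).

    Fits one normative model per PC feature and scores every subject in
    ``pc``. By default the models are fitted on the full given cohort, so
    calling this once per diagnostic group scores each group against its
    own model. Passing ``fit_mask`` (boolean per row) restricts fitting to
    a reference subset (e.g. the TD group) while still scoring everyone —
    the convention that preserves diagnosis-related PC deviations for
    downstream mediation.
    """
    config = config or NormativeConfig()
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    if fit_mask is None:
        fit_mask = np.ones(len(pc), dtype=bool)
    else:
        fit_mask = np.asarray(fit_mask, dtype=bool)
    out = {}
    models = {}
    for col in pc.columns:
        v = pc[col].to_numpy(float)
        try:
            m = fit_normative(v[fit_mask], age[fit_mask], sex[fit_mask],
                              config)
        except ValueError as err:
            warnings.warn(f"PC feature {col!r} not modeled: {err}",
                          stacklevel=2)
            continue
        models[col] = m
        out[col] = centile_scores(m, v, age, sex)
    if not out:
        raise ValueError("no PC feature could be modeled")
    return pd.DataFrame(out, index=pc.index), models


def pc_age_trend(pc: pd.DataFrame, age, sex,
                 config: NormativeConfig | None = None) -> pd.DataFrame:
    """Age-effect LR test per PC summary, BH-corrected across features."""
    config = config or NormativeConfig()
    rows = []
    for col in pc.columns:
        res = age_effect_test(pc[col].to_numpy(float), age, sex, config)
        rows.append({"feature": col, "statistic": res.statistic,
                     "df": res.df, "p": res.p})
    out = pd.DataFrame(rows)
    out["q"] = fdr_bh(out["p"])
    return out
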