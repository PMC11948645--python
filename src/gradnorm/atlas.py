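"""Parcel atlas with canonical 7-network labels.

A :class:`ParcelAtlas` binds an ordered list of cortical parcels to one of
the seven canonical resting-state networks (Yeo-Krienen scheme). Downstream
modules use the network partition both for summarizing deviation maps and
as the module assignment for graph segregation measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical network names, ordered sensory -> transmodal.
NETWORKS: tuple[str, ...] = (
    "Visual",
    "Somatomotor",
    "DorsalAttention",
    "VentralAttention",
    "Limbic",
    "Control",
    "DMN",
)

#: Default share of parcels per network, loosely matching the relative sizes
#: of the seven networks in a 200-parcel cortical parcellation.
DEFAULT_PROPORTIONS: dict[str, float] = {
    "Visual": 0.155,
    "Somatomotor": 0.165,
    "DorsalAttention": 0.13,
    "VentralAttention": 0.11,
    "Limbic": 0.06,
    "Control": 0.145,
    "DMN": 0.235,
}


@dataclass(frozen=True)
class ParcelAtlas:
    """Ordered parcels with a (total, exhaustive) 7-network labelling."""

    parcel_ids: tuple[str, ...]
    network_of: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        missing = [p for p in self.parcel_ids if p not in self.network_of]
        if missing:
            raise ValueError(f"parcels without a network label: {missing[:5]}")
        bad = sorted(set(self.network_of.values()) - set(NETWORKS))
        if bad:
            raise ValueError(f"unknown networks: {bad}")
        if len(self.parcel_ids) >= 2 * len(NETWORKS):
            empty = [n for n in NETWORKS if n not in set(self.network_of.values())]
            if empty:
                raise ValueError(f"empty networks: {empty}")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    @property
    def networks(self) -> tuple[str, ...]:
        return NETWORKS

    def labels(self) -> np.ndarray:
        """Network label per parcel, in parcel order."""
        return np.array([self.network_of[p] for p in self.parcel_ids])

    def indices(self, network: str) -> np.ndarray:
        """Positional indices of the parcels belonging to ``network``."""
        lab = self.labels()
        return np.flatnonzero(lab == network)

    def module_index(self) -> np.ndarray:
        """Integer module assignment per parcel (index into :data:`NETWORKS`)."""
        order = {n: i for i, n in enumerate(NETWORKS)}
        return np.array([order[self.network_of[p]] for p in self.parcel_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parcel_id": list(self.parcel_ids), "network": self.labels()}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ParcelAtlas":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(
            parcel_ids=tuple(df["parcel_id"]),
            network_of=dict(zip(df["parcel_id"], df["network"])),
        )


def make_atlas(P: int = 200, network_sizes: dict[str, int] | None = None) -> ParcelAtlas:
    """Build a deterministic atlas of ``P`` parcels in contiguous network blocks.

    Parameters
    ----------
    P:
        Number of parcels; must be at least 2 per network (14).
    network_sizes:
        Optional explicit parcel count per network; must sum to ``P``.
        Default: proportional split (largest-remainder rounding) following
        :data:`DEFAULT_PROPORTIONS`.
    """
    n_net = len(NETWORKS)
    if P < n_net:
        raise ValueError(f"P={P} is smaller than the number of networks ({n_net})")
    if network_sizes is None:
        network_sizes = _proportional_sizes(P)
    if set(network_sizes) != set(NETWORKS):
        raise ValueError("network_sizes must cover exactly the 7 canonical networks")
    if sum(network_sizes.values()) != P:
        raise ValueError("network_sizes must sum to P")
    parcel_ids: list[str] = []
    network_of: dict[str, str] = {}
    for net in NETWORKS:
        for j in range(network_sizes[net]):
            pid = f"{net}_{j + 1:03d}"
            parcel_ids.append(pid)
            network_of[pid] = net
    return ParcelAtlas(parcel_ids=tuple(parcel_ids), network_of=network_of)


def _proportional_sizes(P: int) -> dict[str, int]:
    # Largest-remainder apportionment with a floor of one parcel per network.
    raw = {n: P * DEFAULT_PROPORTIONS[n] for n in NETWORKS}
    sizes = {n: max(1, int(np.floor(raw[n]))) for n in NETWORKS}
    rem = P - sum(sizes.values())
    if rem < 0:  # tiny P: trim the largest networks
        for n in sorted(NETWORKS, key=lambda n: -sizes[n]):
            while rem < 0 and sizes[n] > 1:
                sizes[n] -= 1
                rem += 1
    frac = sorted(NETWORKS, key=lambda n: (sizes[n] - raw[n], NETWORKS.index(n)))
    i = 0
    while rem > 0:
        sizes[frac[i % len(frac)]] += 1
        rem -= 1
        i += 1
    return sizes
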