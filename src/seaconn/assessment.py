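"""Protected-area network assessment against random-allocation expectation.

For every species and every biodiversity feature (habitat amounts,
connectivity exports, vulnerable imports) the assessment measures the
fraction of the feature's total that falls inside the MPA network —
once for the full network (any protection) and once for the strict
network (IUCN Ia/Ib/II only). Each fraction is compared with the
expectation under random MPA placement, which is simply the network's
area fraction of the study area (all water cells): protection above it
indicates positive siting bias toward the feature, below it the
residual-reservation pattern of avoiding valuable areas.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import FeatureLayer
from .core import MPAStatusLayer

__all__ = ["protection_fraction", "random_expectation", "assess_network"]

NETWORKS = ("full", "strict")


def protection_fraction(feature: FeatureLayer, mpa: MPAStatusLayer,
                        network: str) -> float:
    """Fraction of a feature's total amount lying in protected cells."""
    total = feature.total
    if total <= 0:
        raise ValueError(
            f"feature {feature.species}/{feature.kind} has zero total amount"
        )
    counted = mpa.counted_mask(network)
    return float(feature.amount[counted].sum() / total)


def random_expectation(mpa: MPAStatusLayer, network: str) -> float:
    """Expected protected fraction under random MPA allocation.

    Equals the network's area fraction of the study area, defined as all
    water cells of the grid.
    """
    water = mpa.grid.water_mask
    n_water = int(water.sum())
    if n_water == 0:
        return 0.0
    counted = mpa.counted_mask(network) & water
    return float(counted.sum() / n_water)


def assess_network(features: Sequence[FeatureLayer],
                   mpa: MPAStatusLayer) -> pd.DataFrame:
    """Assess every feature under the full and strict networks.

    Returns one row per species x feature kind x network with the
    protected fraction, the random expectation, and whether protection
    exceeds it, followed by summary rows (``is_summary`` flag) holding
    the unweighted mean protected fraction across species per feature
    kind and network.
    """
    if not features:
        raise ValueError("assessment requires at least one feature layer")
    rows = []
    for f in features:
        for network in NETWORKS:
            frac = protection_fraction(f, mpa, network)
            expect = random_expectation(mpa, network)
            rows.append({
                "species": f.species, "feature_kind": f.kind,
                "network": network, "protected_fraction": frac,
                "random_expectation": expect,
                "exceeds_random": frac > expect,
                "is_summary": False,
            })
    records = pd.DataFrame(rows)
    summaries = (
        records.groupby(["feature_kind", "network"], as_index=False)
        .agg(protected_fraction=("protected_fraction", "mean"),
             random_expectation=("random_expectation", "mean"))
    )
    summaries["species"] = "MEAN"
    summaries["exceeds_random"] = (
        summaries["protected_fraction"] > summaries["random_expectation"]
    )
    summaries["is_summary"] = True
    return pd.concat([records, summaries[records.columns]],
                     ignore_index=True)
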