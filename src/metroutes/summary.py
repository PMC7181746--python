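"""Spread-mode classification and cohort summary statistics.

The metastatic network has five layers ordered T < P < I < C < LM. A route
to the adjacent deeper layer is inter-layer sequential spread; a route
jumping beyond the adjacent layer is inter-layer skip spread; a route
within one layer is intra-layer spread. Percentages are reported to one
decimal place with half-up rounding so that printed counts reproduce
exactly (38 of 61 -> 62.3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

from .model import (
    ContractError,
    LAYER_RANK,
    Lesion,
    MutationCall,
    PatientDataset,
    Route,
)

__all__ = [
    "classify_mode",
    "percentage",
    "summarize_routes",
    "shared_mutation_fractions",
    "RouteSummary",
    "SharingSummary",
]

SEQUENTIAL = "sequential"
SKIP = "skip"
INTRA = "intra"


def classify_mode(route: Route, lesion_layers: Mapping[str, str]) -> str:
    """Classify one route as sequential, skip, or intra-layer spread."""
    src = LAYER_RANK[lesion_layers[route.source_lesion_id]]
    tgt = LAYER_RANK[lesion_layers[route.target_lesion_id]]
    if tgt < src:
        raise ContractError(
            f"route {route.source_lesion_id}->{route.target_lesion_id} runs "
            "against the layer order"
        )
    if tgt == src:
        return INTRA
    if tgt == src + 1:
        return SEQUENTIAL
    return SKIP


def percentage(count: int, total: int) -> float:
    """count/total as a percentage, one decimal, half-up (0.0 when total=0)."""
    if total == 0:
        return 0.0
    pct = Decimal(100) * Decimal(count) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class RouteSummary:
    """Counts and percentages of routes by origin, mode, and seeding class."""

    n_routes: int
    by_origin: Dict[str, int]
    by_mode: Dict[str, int]
    by_seeding: Dict[str, int]
    pct_origin: Dict[str, float] = field(default_factory=dict)
    pct_mode: Dict[str, float] = field(default_factory=dict)
    pct_seeding: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for counts, pcts in (
            (self.by_origin, self.pct_origin),
            (self.by_mode, self.pct_mode),
            (self.by_seeding, self.pct_seeding),
        ):
            if sum(counts.values()) != self.n_routes:
                raise ContractError("summary counts must sum to n_routes")
            for k, v in counts.items():
                pcts[k] = percentage(v, self.n_routes)

    def as_dict(self) -> dict:
        return {
            "n_routes": self.n_routes,
            "by_origin": dict(self.by_origin),
            "by_mode": dict(self.by_mode),
            "by_seeding": dict(self.by_seeding),
            "pct_origin": dict(self.pct_origin),
            "pct_mode": dict(self.pct_mode),
            "pct_seeding": dict(self.pct_seeding),
        }


def summarize_routes(
    routes: Sequence[Route], lesion_layers: Mapping[str, str]
) -> RouteSummary:
    """Tabulate routes by origin (primary / LNM / LM), spread mode, and
    monoclonal vs multiclonal seeding."""
    origin = {"primary": 0, "lnm": 0, "lm": 0}
    mode = {SEQUENTIAL: 0, SKIP: 0, INTRA: 0}
    seeding = {"monoclonal": 0, "multiclonal": 0}
    for r in routes:
        src_layer = lesion_layers[r.source_lesion_id]
        if src_layer == "T":
            origin["primary"] += 1
        elif src_layer == "LM":
            origin["lm"] += 1
        else:
            origin["lnm"] += 1
        mode[r.mode if r.mode else classify_mode(r, lesion_layers)] += 1
        seeding[r.classification] += 1
    return RouteSummary(
        n_routes=len(routes), by_origin=origin, by_mode=mode, by_seeding=seeding
    )


@dataclass
class SharingSummary:
    """Partition of a patient's mutation universe by sample sharing."""

    n_mutations: int
    pct_shared_all: float
    pct_shared_some: float  # in >= 2 samples but not all
    pct_private: float
    pct_primary_met_shared: float

    def as_dict(self) -> dict:
        return {
            "n_mutations": self.n_mutations,
            "pct_shared_all": self.pct_shared_all,
            "pct_shared_some": self.pct_shared_some,
            "pct_private": self.pct_private,
            "pct_primary_met_shared": self.pct_primary_met_shared,
        }


def shared_mutation_fractions(dataset: PatientDataset) -> SharingSummary:
    """Fractions of mutations shared by all samples, by two or more samples,
    or private to one sample; plus the fraction present in both the primary
    lesion and at least one metastasis.

    Presence is binary: a mutation is present in a sample when it was called
    there with a CCF above zero.
    """
    samples = [
        sid for l in dataset.lesions for sid in l.region_sample_ids
    ]
    if len(samples) < 2:
        raise ContractError("sharing fractions need at least two samples")
    primary_samples = set(dataset.primary.region_sample_ids)
    presence: Dict[str, set] = {}
    for m in dataset.mutations:
        if m.ccf > 0:
            presence.setdefault(m.mutation_id, set()).add(m.sample_id)
    n = len(presence)
    if n == 0:
        raise ContractError("no mutations present in any sample")
    n_all = n_some = n_private = n_pm = 0
    n_samples = len(samples)
    for mid, carried in presence.items():
        if len(carried) == n_samples:
            n_all += 1
        elif len(carried) >= 2:
            n_some += 1
        else:
            n_private += 1
        if carried & primary_samples and carried - primary_samples:
            n_pm += 1
    return SharingSummary(
        n_mutations=n,
        pct_shared_all=percentage(n_all, n),
        pct_shared_some=percentage(n_some, n),
        pct_private=percentage(n_private, n),
        pct_primary_met_shared=percentage(n_pm, n),
    )
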