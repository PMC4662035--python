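"""Cross-sample background polymorphism filtering.

Variants shared by a sufficient fraction of independently called units
(lines, or tier-2 pools in amplicon mode) are treated as cultivar
polymorphisms against the reference rather than induced mutations, and
removed from the candidate set. Relaxed call sets should feed the filter
so borderline polymorphisms missed by stringent calling are still caught.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

Site = tuple[str, int, str]  # (seq_name, pos, alt)


@dataclass(frozen=True)
class FilterConfig:
    common_threshold: float = 0.20  # fraction of units sharing a variant
    min_units: int = 2
    use_relaxed_sets: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.common_threshold <= 1:
            raise ValueError("common_threshold must be in (0, 1]")
        if self.min_units < 1:
            raise ValueError("min_units must be >= 1")


def build_background_filter(call_sets: Iterable[set[Site]],
                            config: FilterConfig | None = None) -> set[Site]:
    """Sites present in >= ceil(common_threshold * n_units) units.

    A floor of ``min_units`` ensures a site seen in a single unit is never
    treated as common, no matter how few units there are.
    """
    config = config or FilterConfig()
    call_sets = [set(s) for s in call_sets]
    n = len(call_sets)
    if n < config.min_units:
        raise ValueError(f"need at least {config.min_units} call sets, got {n}")
    required = max(config.min_units,
                   math.ceil(config.common_threshold * n - 1e-12))
    counts: dict[Site, int] = {}
    for s in call_sets:
        for site in s:
            counts[site] = counts.get(site, 0) + 1
    return {site for site, c in counts.items() if c >= required}


def apply_background_filter(calls, filter_set: set[Site]):
    """Remove calls whose (seq, pos, alt) is in the filter set.

    Works on any iterable of objects exposing a ``site`` attribute (e.g.
    PoolVariantCall) or of bare (seq, pos, alt) tuples. Idempotent.
    """
    kept = []
    removed = 0
    for call in calls:
        site = call.site if hasattr(call, "site") else tuple(call)
        if site in filter_set:
            removed += 1
        else:
            kept.append(call)
    return kept, removed
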