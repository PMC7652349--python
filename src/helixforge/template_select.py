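"""Template ranking, the 40% identity ceiling, and identity binning.

Low-identity comparative modeling deliberately excludes templates at or
above 40% sequence identity to the target (the remaining pool mirrors the
common real-world situation for receptors without a close homolog), ranks
the rest by identity, and models from the top few — five by default, the
number that performs best on average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import math

import pandas as pd

from .errors import SelectionError, ValidationError

#: identity bins (inclusive integer percent ranges) used to probe how far
#: down in identity templates remain useful
DEFAULT_BINS: Tuple[Tuple[int, int], ...] = ((15, 19), (20, 24), (25, 29), (30, 39))


@dataclass
class TemplateRanking:
    """Identity-ranked candidate templates for one target."""

    target_id: str
    ranked: List[Tuple[str, float]]  # (template id, % identity), descending
    threshold_max: float = 40.0
    threshold_min: Optional[float] = None

    def ids(self) -> List[str]:
        return [t for t, _ in self.ranked]

    def identity(self, template_id: str) -> float:
        for t, ident in self.ranked:
            if t == template_id:
                return ident
        raise KeyError(template_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranked, columns=["template", "identity"])


def rank_templates(identity_row: Mapping[str, float], threshold_max: float = 40.0,
                   threshold_min: Optional[float] = None,
                   target_id: str = "target") -> TemplateRanking:
    """Filter and rank a target's identity row.

    Templates with identity >= ``threshold_max`` are removed (too close to
    the target for a low-identity benchmark), the remainder sorted by
    descending identity with ties broken lexicographically by id. NaN
    identities (no shared columns) are dropped.
    """
    if hasattr(identity_row, "items"):
        items = list(identity_row.items())
    else:
        raise ValidationError("identity_row must be a mapping id -> % identity")
    kept = []
    for tid, ident in items:
        if tid == target_id or ident is None or (
            isinstance(ident, float) and math.isnan(ident)
        ):
            continue
        if ident >= threshold_max:
            continue
        if threshold_min is not None and ident < threshold_min:
            continue
        kept.append((tid, float(ident)))
    if not kept:
        raise SelectionError(
            f"{target_id}: no templates below {threshold_max}% identity; "
            "raise --max-identity or provide more templates"
        )
    kept.sort(key=lambda item: (-item[1], item[0]))
    return TemplateRanking(
        target_id=target_id, ranked=kept,
        threshold_max=threshold_max, threshold_min=threshold_min,
    )


def select_top_n(ranking: TemplateRanking, n: int = 5) -> List[str]:
    """The ``min(n, pool)`` highest-identity template ids. Five templates is
    the default modeling set size."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if not ranking.ranked:
        raise SelectionError("empty ranking")
    return ranking.ids()[:n]


def bin_templates(ranking: TemplateRanking,
                  bins: Sequence[Tuple[int, int]] = DEFAULT_BINS
                  ) -> Dict[str, List[str]]:
    """Partition ranked templates into inclusive integer identity bins.

    Identity is truncated to integer percent before range testing, so
    24.9% falls in the 20-24 bin. Templates outside every bin are returned
    under the ``"unbinned"`` key. Overlapping bins are a config error.
    """
    spans = sorted(bins)
    for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
        if hi1 >= lo2:
            raise ValidationError(f"overlapping bins: {(lo1, hi1)} and {(lo2, hi2)}")
    out: Dict[str, List[str]] = {f"{lo}-{hi}": [] for lo, hi in bins}
    out["unbinned"] = []
    for tid, ident in ranking.ranked:
        trunc = int(ident)
        for lo, hi in bins:
            if lo <= trunc <= hi:
                out[f"{lo}-{hi}"].append(tid)
                break
        else:
            out["unbinned"].append(tid)
    return out
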