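"""Core sample-level container for multiplexed count profiles."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

from .panel import PanelError, ProbePanel

__all__ = ["CountProfile"]


@dataclass
class CountProfile:
    """One sample's raw digital counts over a probe panel.

    Counts are non-negative integers keyed by probe id. ``metadata`` carries
    free-form annotations (collection date, cohort arm, tumor fraction for
    simulated samples, ...).
    """

    sample_id: str
    counts: dict[str, int]
    fluid: str = "plasma"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for probe_id, count in self.counts.items():
            if not float(count).is_integer() or count < 0:
                raise ValueError(
                    f"{self.sample_id}: count for {probe_id!r} must be a "
                    f"non-negative integer, got {count!r}"
                )
        self.counts = {k: int(v) for k, v in self.counts.items()}

    def require_panel(self, panel: ProbePanel) -> None:
        """Raise :class:`PanelError` if any panel probe lacks a count."""
        missing = [p for p in panel.ids() if p not in self.counts]
        if missing:
            raise PanelError(f"{self.sample_id}: missing counts for probes {missing}")

    def subset(self, probe_ids: Mapping[str, Any] | list[str]) -> list[int]:
        return [self.counts[p] for p in probe_ids]
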