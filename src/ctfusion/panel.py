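"""Probe panel model for the multiplexed fusion/splice-variant count assay.

The panel mirrors a custom digital-barcoding codeset for liquid-biopsy
detection of recurrent kinase-fusion transcripts in non-small-cell lung
cancer: 23 fusion-junction probes (7 ALK, 10 ROS1, 6 RET), probes for
wild-type MET and the MET exon-14-skipping transcript, 3 housekeeping
probes (GAPDH, MRPL19, PSMC4) acting as an RNA-quantity QC gate, and 6
no-target negative-control probes that measure nonspecific background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "ProbeClass",
    "Probe",
    "ProbePanel",
    "default_panel",
    "PanelError",
]


class PanelError(ValueError):
    """Raised for malformed panels or probe/panel mismatches."""


#: valid probe classes
PROBE_CLASSES = ("fusion", "housekeeping", "negative_control", "met_wt", "met_skip")


class ProbeClass:
    FUSION = "fusion"
    HOUSEKEEPING = "housekeeping"
    NEGATIVE_CONTROL = "negative_control"
    MET_WT = "met_wt"
    MET_SKIP = "met_skip"


@dataclass(frozen=True)
class Probe:
    """One reporter probe.

    ``variant`` uses the exon-junction shorthand of the field, e.g.
    ``"E13:A20"`` for the EML4 exon 13 / ALK exon 20 junction (EML4-ALK v1).
    """

    probe_id: str
    probe_class: str
    gene: str = ""
    variant: str = ""

    def __post_init__(self) -> None:
        if self.probe_class not in PROBE_CLASSES:
            raise PanelError(f"unknown probe class {self.probe_class!r} for {self.probe_id!r}")


@dataclass
class ProbePanel:
    """An ordered probe catalogue with class-based accessors."""

    probes: list[Probe] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.probe_id for p in self.probes]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelError(f"duplicate probe ids: {dupes}")
        self._by_id = {p.probe_id: p for p in self.probes}

    def __iter__(self) -> Iterator[Probe]:
        return iter(self.probes)

    def __len__(self) -> int:
        return len(self.probes)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self._by_id

    def __getitem__(self, probe_id: str) -> Probe:
        try:
            return self._by_id[probe_id]
        except KeyError:
            raise PanelError(f"probe {probe_id!r} not in panel") from None

    def ids(self, probe_class: str | None = None) -> list[str]:
        if probe_class is None:
            return [p.probe_id for p in self.probes]
        return [p.probe_id for p in self.probes if p.probe_class == probe_class]

    @property
    def fusion_ids(self) -> list[str]:
        return self.ids(ProbeClass.FUSION)

    @property
    def housekeeping_ids(self) -> list[str]:
        return self.ids(ProbeClass.HOUSEKEEPING)

    @property
    def negative_control_ids(self) -> list[str]:
        return self.ids(ProbeClass.NEGATIVE_CONTROL)

    @property
    def met_wt_id(self) -> str:
        ids = self.ids(ProbeClass.MET_WT)
        if len(ids) != 1:
            raise PanelError(f"panel must carry exactly one met_wt probe, found {len(ids)}")
        return ids[0]

    @property
    def met_skip_id(self) -> str:
        ids = self.ids(ProbeClass.MET_SKIP)
        if len(ids) != 1:
            raise PanelError(f"panel must carry exactly one met_skip probe, found {len(ids)}")
        return ids[0]

    def gene_of(self, probe_id: str) -> str:
        return self[probe_id].gene

    def target_ids(self) -> list[str]:
        """Probe ids that can be a sample's true alteration (fusions + MET skip)."""
        return self.fusion_ids + [self.met_skip_id]


def _fusions(gene: str, partner_variants: Iterable[tuple[str, str]]) -> list[Probe]:
    out = []
    for partner, junction in partner_variants:
        out.append(
            Probe(
                probe_id=f"{gene}_{partner}_{junction}",
                probe_class=ProbeClass.FUSION,
                gene=gene,
                variant=junction,
            )
        )
    return out


def default_panel() -> ProbePanel:
    """Build the default 34-probe panel.

    Junction labels are a synthetic reconstruction of a recurrent-fusion
    codeset (the common EML4-ALK, CD74/SLC34A2/SDC4-ROS1 and
    KIF5B/CCDC6-RET junctions plus rarer partners), not a vendor file.
    """
    probes: list[Probe] = []
    # 7 ALK fusion-junction probes; EML4-ALK v1 (E13:A20) is the most common.
    probes += _fusions(
        "ALK",
        [
            ("EML4", "E13:A20"),   # v1
            ("EML4", "E20:A20"),   # v2
            ("EML4", "E6:A20"),    # v3a/b
            ("EML4", "E18:A20"),   # v5
            ("EML4", "E2:A20"),    # v5a
            ("KIF5B", "K17:A20"),
            ("TFG", "T5:A20"),
        ],
    )
    # 10 ROS1 probes.
    probes += _fusions(
        "ROS1",
        [
            ("CD74", "C6:R32"),
            ("CD74", "C6:R34"),
            ("SLC34A2", "S4:R32"),
            ("SLC34A2", "S4:R34"),
            ("SLC34A2", "S13:R32"),
            ("SDC4", "S2:R32"),
            ("SDC4", "S2:R34"),
            ("EZR", "E10:R34"),
            ("TPM3", "T8:R35"),
            ("GOPC", "G8:R35"),
        ],
    )
    # 6 RET probes.
    probes += _fusions(
        "RET",
        [
            ("KIF5B", "K15:R12"),
            ("KIF5B", "K16:R12"),
            ("KIF5B", "K22:R12"),
            ("CCDC6", "C1:R12"),
            ("NCOA4", "N7:R12"),
            ("TRIM33", "T14:R12"),
        ],
    )
    probes.append(Probe("MET_wt", ProbeClass.MET_WT, gene="MET", variant="wt"))
    probes.append(Probe("MET_delta14", ProbeClass.MET_SKIP, gene="MET", variant="d14"))
    for hk in ("GAPDH", "MRPL19", "PSMC4"):
        probes.append(Probe(hk, ProbeClass.HOUSEKEEPING, gene=hk))
    for letter in "ABCDEF":
        probes.append(Probe(f"NEG_{letter}", ProbeClass.NEGATIVE_CONTROL))
    return ProbePanel(probes)


#: canonical (most recurrent) target probe per gene, used when a cohort spec
#: gives only the gene of an alteration
CANONICAL_TARGET = {
    "ALK": "ALK_EML4_E13:A20",
    "ROS1": "ROS1_CD74_C6:R32",
    "RET": "RET_KIF5B_K15:R12",
    "MET": "MET_delta14",
}
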