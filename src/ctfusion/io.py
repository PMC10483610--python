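"""Readers and writers for the pipeline's plain-text formats.

Formats
-------
* **Sectioned count-profile CSV** (an RCC-like dialect): ``<Header>``,
  ``<Sample_Attributes>`` and ``<Code_Summary>`` sections; the code summary
  has columns ``CodeClass,Name,Accession,Count`` with CodeClass one of
  ``Endogenous`` (fusion and MET probes), ``Housekeeping`` or ``Negative``.
* **Panel TSV**: ``probe_id  code_class  gene  variant``.
* **Chip summary CSV**: ``sample_id,assay,n_partitions,n_mut_only,
  n_ref_only,n_double,n_neg``.
* **Manifest TSV**: ``sample_id  alteration  tumor_fraction  fluid``.
* **Longitudinal TSV**: ``patient_id  ordinal  copies_per_ul  [counts]
  [response]``.
* **RunConfig YAML**: every tunable threshold with its default.

Counts are integers; fractional counts are rejected, not rounded.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .calling import FusionCallSet, QcResult
from .dpcr import ChipReadout, QuantResult
from .monitoring import TimePoint
from .panel import Probe, ProbePanel
from .profiles import CountProfile
from .simulate import AssayTruth, CohortSample, SimulationConfig

__all__ = [
    "ParseError",
    "RunConfig",
    "read_rcc_dialect",
    "write_rcc_dialect",
    "read_panel_tsv",
    "write_panel_tsv",
    "read_chips_csv",
    "write_chips_csv",
    "read_manifest_tsv",
    "write_manifest_tsv",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_series_tsv",
    "write_calls_tsv",
    "write_quant_tsv",
    "write_qc_tsv",
    "write_cohort",
    "config_hash",
]


class ParseError(ValueError):
    """Malformed input file; message carries the file and line number."""


# ---------------------------------------------------------------------------
# sectioned count-profile CSV

_CODECLASS_OF_PROBE_CLASS = {
    "fusion": "Endogenous",
    "met_wt": "Endogenous",
    "met_skip": "Endogenous",
    "housekeeping": "Housekeeping",
    "negative_control": "Negative",
}
_KNOWN_CODECLASSES = {"Endogenous", "Housekeeping", "Negative"}


def read_rcc_dialect(path: str | Path) -> CountProfile:
    """Parse one sample's sectioned count-profile CSV into a CountProfile."""
    path = Path(path)
    sections: dict[str, list[tuple[int, list[str]]]] = {}
    current: str | None = None
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            cell = row[0].strip()
            if cell.startswith("<") and cell.endswith(">"):
                current = cell[1:-1]
                sections[current] = []
                continue
            if current is None:
                raise ParseError(f"{path}:{lineno}: data before any <section> header")
            sections[current].append((lineno, row))
    for required in ("Header", "Code_Summary"):
        if required not in sections:
            raise ParseError(f"{path}: missing <{required}> section")
    attrs = {row[0].strip(): (row[1].strip() if len(row) > 1 else "")
             for _, row in sections.get("Sample_Attributes", [])}
    sample_id = attrs.pop("ID", path.stem)
    fluid = attrs.pop("Fluid", "plasma")

    code_rows = sections["Code_Summary"]
    if not code_rows:
        raise ParseError(f"{path}: empty <Code_Summary> section")
    header_line, header = code_rows[0]
    cols = [c.strip() for c in header]
    for needed in ("CodeClass", "Name", "Count"):
        if needed not in cols:
            raise ParseError(f"{path}:{header_line}: <Code_Summary> lacks column {needed!r}")
    i_class, i_name, i_count = cols.index("CodeClass"), cols.index("Name"), cols.index("Count")
    counts: dict[str, int] = {}
    for lineno, row in code_rows[1:]:
        if len(row) < len(cols):
            raise ParseError(f"{path}:{lineno}: short row in <Code_Summary>")
        code_class, name, raw = row[i_class].strip(), row[i_name].strip(), row[i_count].strip()
        if code_class not in _KNOWN_CODECLASSES:
            raise ParseError(f"{path}:{lineno}: unknown CodeClass {code_class!r}")
        if name in counts:
            raise ParseError(f"{path}:{lineno}: duplicate probe {name!r}")
        try:
            value = float(raw)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric count {raw!r}") from None
        if not value.is_integer() or value < 0:
            raise ParseError(
                f"{path}:{lineno}: count for {name!r} must be a non-negative integer, got {raw}"
            )
        counts[name] = int(value)
    metadata = {k.lower(): v for k, v in attrs.items()}
    return CountProfile(sample_id=sample_id, counts=counts, fluid=fluid, metadata=metadata)


def write_rcc_dialect(profile: CountProfile, panel: ProbePanel, path: str | Path) -> None:
    """Write a CountProfile in the sectioned CSV dialect (panel order)."""
    profile.require_panel(panel)
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["<Header>"])
        w.writerow(["FileVersion", "1.0"])
        w.writerow(["<Sample_Attributes>"])
        w.writerow(["ID", profile.sample_id])
        w.writerow(["Fluid", profile.fluid])
        for key, value in sorted(profile.metadata.items()):
            w.writerow([key.capitalize(), value])
        w.writerow(["<Code_Summary>"])
        w.writerow(["CodeClass", "Name", "Accession", "Count"])
        for probe in panel:
            w.writerow(
                [
                    _CODECLASS_OF_PROBE_CLASS[probe.probe_class],
                    probe.probe_id,
                    "",
                    profile.counts[probe.probe_id],
                ]
            )


# ---------------------------------------------------------------------------
# simple tabular formats

def read_panel_tsv(path: str | Path) -> ProbePanel:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("probe_id", "code_class"):
        if col not in df.columns:
            raise ParseError(f"{path}: panel TSV lacks column {col!r}")
    probes = [
        Probe(
            probe_id=row.probe_id,
            probe_class=row.code_class,
            gene=getattr(row, "gene", ""),
            variant=getattr(row, "variant", ""),
        )
        for row in df.itertuples(index=False)
    ]
    return ProbePanel(probes)


def write_panel_tsv(panel: ProbePanel, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"probe_id": p.probe_id, "code_class": p.probe_class, "gene": p.gene, "variant": p.variant}
            for p in panel
        ]
    ).to_csv(path, sep="\t", index=False)


def read_chips_csv(path: str | Path) -> list[ChipReadout]:
    df = pd.read_csv(path)
    needed = {"sample_id", "assay", "n_partitions", "n_mut_only", "n_ref_only", "n_double", "n_neg"}
    missing = needed - set(df.columns)
    if missing:
        raise ParseError(f"{path}: chip CSV lacks columns {sorted(missing)}")
    return [
        ChipReadout(
            sample_id=str(r.sample_id),
            assay=str(r.assay),
            n_partitions=int(r.n_partitions),
            n_mut_only=int(r.n_mut_only),
            n_ref_only=int(r.n_ref_only),
            n_double=int(r.n_double),
            n_neg=int(r.n_neg),
        )
        for r in df.itertuples(index=False)
    ]


def write_chips_csv(chips: Sequence[ChipReadout], path: str | Path) -> None:
    pd.DataFrame([asdict(c) for c in chips]).to_csv(path, index=False)


def read_manifest_tsv(path: str | Path) -> list[AssayTruth]:
    df = pd.read_csv(path, sep="\t")
    return [
        AssayTruth(
            sample_id=str(r.sample_id),
            alteration=str(r.alteration),
            tumor_fraction=float(r.tumor_fraction),
            fluid=str(r.fluid),
        )
        for r in df.itertuples(index=False)
    ]


def write_manifest_tsv(truths: Iterable[AssayTruth], path: str | Path) -> None:
    pd.DataFrame([asdict(t) for t in truths]).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path, sample_id: str | None = None) -> CountProfile:
    """Plain two-column ``probe_id<TAB>count`` profile."""
    path = Path(path)
    counts: dict[str, int] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'probe_id<TAB>count'")
            pid, raw = parts[0].strip(), parts[1].strip()
            if lineno == 1 and pid == "probe_id":
                continue
            if pid in counts:
                raise ParseError(f"{path}:{lineno}: duplicate probe {pid!r}")
            try:
                value = float(raw)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric count {raw!r}") from None
            if not value.is_integer() or value < 0:
                raise ParseError(f"{path}:{lineno}: count must be a non-negative integer, got {raw}")
            counts[pid] = int(value)
    return CountProfile(sample_id=sample_id or path.stem, counts=counts)


def write_counts_tsv(profile: CountProfile, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("probe_id\tcount\n")
        for pid, count in profile.counts.items():
            fh.write(f"{pid}\t{count}\n")


def read_series_tsv(path: str | Path) -> dict[str, list[TimePoint]]:
    """Longitudinal TSV -> timepoints per patient, ordered as given."""
    df = pd.read_csv(path, sep="\t")
    for col in ("patient_id", "ordinal", "copies_per_ul"):
        if col not in df.columns:
            raise ParseError(f"{path}: longitudinal TSV lacks column {col!r}")
    series: dict[str, list[TimePoint]] = {}
    for r in df.itertuples(index=False):
        counts = getattr(r, "counts", None)
        response = getattr(r, "response", "unknown")
        series.setdefault(str(r.patient_id), []).append(
            TimePoint(
                sample_id=f"{r.patient_id}@{r.ordinal}",
                ordinal=float(r.ordinal),
                copies_per_ul=float(r.copies_per_ul),
                counts=None if counts is None or pd.isna(counts) else int(counts),
                response="unknown" if pd.isna(response) else str(response),
            )
        )
    return series


def write_qc_tsv(results: Sequence[QcResult], path: str | Path) -> None:
    pd.DataFrame([asdict(r) for r in results]).to_csv(path, sep="\t", index=False)


def write_calls_tsv(calls: Sequence[FusionCallSet], path: str | Path) -> None:
    rows = []
    for c in calls:
        rows.append(
            {
                "sample_id": c.sample_id,
                "evaluable": c.evaluable,
                "overall_alteration": c.overall_alteration,
                "overall_gene": c.overall_gene,
                "met_ratio": "" if c.met_ratio is None else f"{c.met_ratio:.4f}",
                "met_call": c.met_call,
                "positives": ";".join(c.positives),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_quant_tsv(results: Sequence[QuantResult], path: str | Path) -> None:
    rows = []
    for q in results:
        rows.append(
            {
                "sample_id": q.sample_id,
                "assay": q.assay,
                "evaluable": q.evaluable,
                "mut_copies_per_ul": q.mutant.copies_per_ul,
                "mut_ci_low": q.mutant.ci_low,
                "mut_ci_high": q.mutant.ci_high,
                "ref_copies_per_ul": q.reference.copies_per_ul,
                "ref_ci_low": q.reference.ci_low,
                "ref_ci_high": q.reference.ci_high,
                "maf": "" if q.maf is None or q.maf.maf is None else q.maf.maf,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_cohort(
    cohort: Sequence[CohortSample],
    config: SimulationConfig,
    panel: ProbePanel,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a simulated cohort: manifest TSV, per-sample sectioned CSV
    profiles, chip summary CSV, and a JSON sidecar with the full generative
    configuration (reproducibility record)."""
    out_dir = Path(out_dir)
    (out_dir / "profiles").mkdir(parents=True, exist_ok=True)
    paths = {
        "manifest": out_dir / "manifest.tsv",
        "chips": out_dir / "chips.csv",
        "config": out_dir / "simulation_config.json",
        "panel": out_dir / "panel.tsv",
    }
    write_manifest_tsv([s.truth for s in cohort], paths["manifest"])
    write_chips_csv([s.chip for s in cohort], paths["chips"])
    write_panel_tsv(panel, paths["panel"])
    for s in cohort:
        write_rcc_dialect(s.profile, panel, out_dir / "profiles" / f"{s.truth.sample_id}.csv")
    with paths["config"].open("w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Every tunable of the pipeline, with its assay default."""

    seed: int = 0
    qc_hk_geomean: float = 30.0
    sd_multiplier: float = 6.0
    met_ratio_cutoff: float = 1.0
    min_reference_copies_per_ul: float = 0.5
    up_fold: float = 2.0
    down_fold: float = 0.2
    ci_method: str = "wilson"
    partition_volume_ul: float = 7.55e-4
    n_reference_negatives: int = 16
    simulation: dict = field(default_factory=dict)   # SimulationConfig overrides

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"{path}: unknown RunConfig keys {sorted(unknown)}")
        return cls(**data)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
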