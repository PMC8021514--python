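"""Domain containers and tabular I/O.

The pipeline works on three tables: a beta-value matrix (probes x samples,
methylation fractions in [0, 1], optionally paired with a detection p-value
matrix of the same shape), an Illumina-manifest-style probe annotation, and
a clinical sample sheet. Everything is pandas-backed; the canonical internal
methylation scale is the fraction scale, percent appears only at I/O and in
marker cut-off display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "BetaMatrix",
    "ProbeAnnotation",
    "ClinicalRecord",
    "CohortDataset",
    "CPG_TYPES",
    "GENE_REGIONS",
    "CHROMOSOMES",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_sample_sheet",
    "write_sample_sheet",
    "clinical_frame",
    "convert_scale",
    "write_results_table",
]


class FormatError(ValueError):
    """A file violated the expected tabular format."""


CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
CPG_TYPES = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
GENE_REGIONS = (
    "TSS1500",
    "TSS200",
    "5'UTR",
    "FirstExon",
    "FirstIntron",
    "GeneBody",
    "Intergenic",
)

# Aliases seen in Illumina manifests and hand-curated tables.
_CPG_TYPE_ALIASES = {
    "island": "Island",
    "n_shore": "N_Shore",
    "s_shore": "S_Shore",
    "n_shelf": "N_Shelf",
    "s_shelf": "S_Shelf",
    "opensea": "OpenSea",
    "open sea": "OpenSea",
    "open_sea": "OpenSea",
    "": "OpenSea",  # manifests leave open-sea probes blank
}
_GENE_REGION_ALIASES = {
    "tss1500": "TSS1500",
    "tss200": "TSS200",
    "5'utr": "5'UTR",
    "5utr": "5'UTR",
    "5_utr": "5'UTR",
    "firstexon": "FirstExon",
    "1stexon": "FirstExon",
    "first exon": "FirstExon",
    "firstintron": "FirstIntron",
    "1stintron": "FirstIntron",
    "first intron": "FirstIntron",
    "genebody": "GeneBody",
    "body": "GeneBody",
    "gene body": "GeneBody",
    "intergenic": "Intergenic",
    "intergenic region": "Intergenic",
    "": "Intergenic",
}

_BETA_TOL = 1e-9


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions with optional detection p-values.

    ``beta`` is indexed by probe id with sample-id columns; NaN marks a
    missing measurement. ``detection_p``, when present, is aligned cell for
    cell with ``beta``.
    """

    beta: pd.DataFrame
    detection_p: Optional[pd.DataFrame] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta = self.beta.astype(float)
        if self.beta.index.has_duplicates:
            dupes = self.beta.index[self.beta.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe ids: {dupes[:5]}")
        if self.beta.columns.has_duplicates:
            dupes = self.beta.columns[self.beta.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes[:5]}")
        values = self.beta.to_numpy()
        bad = (values < -_BETA_TOL) | (values > 1.0 + _BETA_TOL)
        if np.any(bad & ~np.isnan(values)):
            i, j = np.argwhere(bad & ~np.isnan(values))[0]
            raise FormatError(
                f"beta value {values[i, j]} outside [0, 1] at probe "
                f"{self.beta.index[i]!r}, sample {self.beta.columns[j]!r}"
            )
        if self.detection_p is not None:
            self.detection_p = self.detection_p.astype(float)
            if not self.detection_p.index.equals(self.beta.index) or not (
                self.detection_p.columns.equals(self.beta.columns)
            ):
                raise FormatError("detection_p ids/shape do not match beta")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.beta.shape

    def subset_probes(self, probes: Sequence[str]) -> "BetaMatrix":
        dp = self.detection_p.loc[list(probes)] if self.detection_p is not None else None
        return BetaMatrix(self.beta.loc[list(probes)], dp, dict(self.metadata))

    def subset_samples(self, samples: Sequence[str]) -> "BetaMatrix":
        dp = self.detection_p[list(samples)] if self.detection_p is not None else None
        return BetaMatrix(self.beta[list(samples)], dp, dict(self.metadata))


@dataclass
class ProbeAnnotation:
    """Manifest-style per-probe annotation with the closed vocabularies.

    ``table`` is indexed by probe id with columns chromosome, position,
    gene_symbol (None when intergenic/unannotated), cpg_type, gene_region.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chromosome", "position", "gene_symbol", "cpg_type", "gene_region"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"annotation missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise FormatError("duplicate probe ids in annotation")
        bad_chr = set(self.table["chromosome"].astype(str)) - set(CHROMOSOMES)
        if bad_chr:
            raise FormatError(f"unknown chromosome tokens: {sorted(bad_chr)}")
        bad_type = set(self.table["cpg_type"]) - set(CPG_TYPES)
        if bad_type:
            raise FormatError(f"unknown CpG-type tokens: {sorted(bad_type)}")
        bad_region = set(self.table["gene_region"]) - set(GENE_REGIONS)
        if bad_region:
            raise FormatError(f"unknown gene-region tokens: {sorted(bad_region)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def sex_probe_ids(self) -> list[str]:
        mask = self.table["chromosome"].astype(str).isin(["X", "Y"])
        return list(self.table.index[mask])


@dataclass
class ClinicalRecord:
    """Per-sample clinical annotation.

    ``tissue_group`` is C (normal control pancreas), N (non-cancerous tissue
    from a cancer patient) or T (tumor). Survival fields are in days from
    surgery and may be absent (None).
    """

    sample_id: str
    patient_id: str
    tissue_group: str
    recurrence: bool
    rfs_days: Optional[float] = None
    os_days: Optional[float] = None
    dead: Optional[bool] = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tissue_group not in ("C", "N", "T"):
            raise FormatError(f"tissue_group must be C/N/T, got {self.tissue_group!r}")
        if self.recurrence and self.rfs_days is None:
            raise FormatError(f"{self.sample_id}: recurrence=True requires rfs_days")
        for name in ("rfs_days", "os_days"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise FormatError(f"{self.sample_id}: {name} must be non-negative")
        if self.rfs_days is not None and self.os_days is not None:
            if self.rfs_days > self.os_days:
                raise FormatError(
                    f"{self.sample_id}: rfs_days {self.rfs_days} > os_days {self.os_days}"
                )


@dataclass
class CohortDataset:
    """A complete cohort: betas + annotation + clinical records."""

    beta: BetaMatrix
    annotation: ProbeAnnotation
    clinical: list[ClinicalRecord]
    methylation_scale: str = "fraction"

    def __post_init__(self) -> None:
        if self.methylation_scale not in ("fraction", "percent"):
            raise FormatError("methylation_scale must be 'fraction' or 'percent'")
        by_sample = {r.sample_id for r in self.clinical}
        missing = set(self.beta.sample_ids) - by_sample
        if missing:
            raise FormatError(f"samples without clinical records: {sorted(missing)[:5]}")
        unannotated = set(self.beta.probe_ids) - set(self.annotation.probe_ids)
        if unannotated:
            raise FormatError(f"probes without annotation: {sorted(unannotated)[:5]}")

    def records_for(self, tissue_group: str) -> list[ClinicalRecord]:
        return [r for r in self.clinical if r.tissue_group == tissue_group]

    def sample_ids_for(self, tissue_group: str) -> list[str]:
        wanted = {r.sample_id for r in self.clinical if r.tissue_group == tissue_group}
        return [s for s in self.beta.sample_ids if s in wanted]


# ---------------------------------------------------------------------------
# readers / writers


def _read_table_tsv(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        rows, index = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_cols:
                raise FormatError(
                    f"{path.name}:{lineno}: expected {n_cols} fields, got {len(fields)}"
                )
            index.append(fields[0])
            rows.append([np.nan if f in ("", "NA") else float(f) for f in fields[1:]])
    frame = pd.DataFrame(rows, index=pd.Index(index, name=header[0]), columns=header[1:])
    return frame


def read_beta_matrix(
    path: Union[str, Path],
    dialect: str = "plain-tsv",
    detection_p_path: Optional[Union[str, Path]] = None,
) -> BetaMatrix:
    """Read a beta matrix from a plain TSV or a GEO-series-matrix-style file.

    plain-tsv: first column probe id, remaining columns one per sample.
    geo-series-matrix: '!'-prefixed metadata lines; the data table sits
    between the ``!series_matrix_table_begin`` / ``_end`` sentinels.
    """
    if dialect == "plain-tsv":
        beta = _read_table_tsv(path)
        metadata: dict = {}
    elif dialect == "geo-series-matrix":
        beta, metadata = _read_geo_series_matrix(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    detection = _read_table_tsv(detection_p_path) if detection_p_path else None
    return BetaMatrix(beta, detection, metadata)


def _read_geo_series_matrix(path: Union[str, Path]) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    metadata: dict = {}
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            stripped = line.rstrip("\n")
            if stripped.lower().startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if stripped.lower().startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(stripped)
            elif stripped.startswith("!"):
                key, _, value = stripped[1:].partition("\t")
                metadata.setdefault(key, []).append(value.strip('"'))
    if not table_lines:
        raise FormatError(f"{path.name}: no series-matrix table sentinels found")
    header = [f.strip('"') for f in table_lines[0].split("\t")]
    rows, index = [], []
    for lineno, line in enumerate(table_lines[1:], start=2):
        fields = [f.strip('"') for f in line.split("\t")]
        if len(fields) != len(header):
            raise FormatError(f"{path.name}: ragged table row {lineno}")
        index.append(fields[0])
        rows.append([np.nan if f in ("", "NA", "null") else float(f) for f in fields[1:]])
    frame = pd.DataFrame(rows, index=pd.Index(index, name=header[0]), columns=header[1:])
    return frame, metadata


def write_beta_matrix(matrix: BetaMatrix, path: Union[str, Path]) -> None:
    """Write the beta (not detection) table as plain TSV at full precision."""
    _write_float_tsv(matrix.beta, path)


def _write_float_tsv(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join([frame.index.name or "probe_id", *map(str, frame.columns)]) + "\n")
        values = frame.to_numpy()
        for i, probe in enumerate(frame.index):
            cells = ("" if np.isnan(v) else repr(float(v)) for v in values[i])
            fh.write(probe + "\t" + "\t".join(cells) + "\n")


_MANIFEST_COLUMN_ALIASES = {
    "ilmnid": "probe_id",
    "probe_id": "probe_id",
    "name": "probe_id",
    "chr": "chromosome",
    "chromosome": "chromosome",
    "mapinfo": "position",
    "position": "position",
    "ucsc_refgene_name": "gene_symbol",
    "gene_symbol": "gene_symbol",
    "relation_to_ucsc_cpg_island": "cpg_type",
    "cpg_type": "cpg_type",
    "ucsc_refgene_group": "gene_region",
    "gene_region": "gene_region",
}


def read_probe_annotation(path: Union[str, Path]) -> ProbeAnnotation:
    """Read a manifest-style CSV, normalizing vocabulary to the closed sets."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {}
    for col in raw.columns:
        key = col.strip().lower()
        if key in _MANIFEST_COLUMN_ALIASES:
            rename[col] = _MANIFEST_COLUMN_ALIASES[key]
    raw = raw.rename(columns=rename)
    required = {"probe_id", "chromosome", "position", "gene_symbol", "cpg_type", "gene_region"}
    missing = required - set(raw.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")

    chrom = raw["chromosome"].str.replace("^chr", "", regex=True).str.strip()
    bad = sorted(set(chrom) - set(CHROMOSOMES))
    if bad:
        raise FormatError(f"unknown chromosome tokens: {bad}")

    def _norm(series: pd.Series, aliases: Mapping[str, str], what: str) -> pd.Series:
        lowered = series.str.strip().str.lower()
        unknown = sorted(set(lowered) - set(aliases))
        if unknown:
            raise FormatError(f"unknown {what} tokens: {unknown}")
        return lowered.map(aliases)

    gene = raw["gene_symbol"].str.strip()
    gene = gene.where(~gene.isin(["", "NA", "na", "N/A"]), None)
    table = pd.DataFrame(
        {
            "chromosome": chrom.to_numpy(),
            "position": raw["position"].astype(int).to_numpy(),
            "gene_symbol": gene.to_numpy(),
            "cpg_type": _norm(raw["cpg_type"], _CPG_TYPE_ALIASES, "CpG-type").to_numpy(),
            "gene_region": _norm(raw["gene_region"], _GENE_REGION_ALIASES, "gene-region").to_numpy(),
        },
        index=pd.Index(raw["probe_id"].str.strip(), name="probe_id"),
    )
    return ProbeAnnotation(table)


def write_probe_annotation(annotation: ProbeAnnotation, path: Union[str, Path]) -> None:
    out = annotation.table.copy()
    out.insert(0, "IlmnID", out.index)
    out = out.rename(
        columns={
            "chromosome": "CHR",
            "position": "MAPINFO",
            "gene_symbol": "UCSC_RefGene_Name",
            "cpg_type": "Relation_to_UCSC_CpG_Island",
            "gene_region": "UCSC_RefGene_Group",
        }
    )
    out["UCSC_RefGene_Name"] = out["UCSC_RefGene_Name"].fillna("NA")
    out.to_csv(path, index=False)


_SHEET_COLUMNS = ("sample_id", "patient_id", "tissue_group", "recurrence", "rfs_days", "os_days", "dead")


def read_sample_sheet(path: Union[str, Path]) -> list[ClinicalRecord]:
    """Read the clinical sample sheet CSV; extra columns become covariates."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(_SHEET_COLUMNS[:4]) - set(raw.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
    records = []
    extra = [c for c in raw.columns if c not in _SHEET_COLUMNS]
    for _, row in raw.iterrows():
        records.append(
            ClinicalRecord(
                sample_id=row["sample_id"],
                patient_id=row["patient_id"],
                tissue_group=row["tissue_group"],
                recurrence=_parse_bool(row["recurrence"], allow_absent=False),
                rfs_days=_parse_float(row.get("rfs_days", "")),
                os_days=_parse_float(row.get("os_days", "")),
                dead=_parse_bool(row.get("dead", ""), allow_absent=True),
                covariates={c: row[c] for c in extra if row[c] != ""},
            )
        )
    return records


def _parse_bool(token: str, allow_absent: bool) -> Optional[bool]:
    token = str(token).strip().lower()
    if token in ("true", "1", "yes"):
        return True
    if token in ("false", "0", "no"):
        return False
    if token in ("", "na") and allow_absent:
        return None
    raise FormatError(f"cannot parse boolean {token!r}")


def _parse_float(token) -> Optional[float]:
    token = str(token).strip()
    if token in ("", "NA", "na"):
        return None
    return float(token)


def write_sample_sheet(records: Iterable[ClinicalRecord], path: Union[str, Path]) -> None:
    rows = []
    covariate_names: list[str] = []
    records = list(records)
    for r in records:
        for name in r.covariates:
            if name not in covariate_names:
                covariate_names.append(name)
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "patient_id": r.patient_id,
            "tissue_group": r.tissue_group,
            "recurrence": str(r.recurrence).lower(),
            "rfs_days": "" if r.rfs_days is None else repr(float(r.rfs_days)),
            "os_days": "" if r.os_days is None else repr(float(r.os_days)),
            "dead": "" if r.dead is None else str(r.dead).lower(),
        }
        for name in covariate_names:
            row[name] = r.covariates.get(name, "")
        rows.append(row)
    pd.DataFrame(rows, columns=list(_SHEET_COLUMNS) + covariate_names).to_csv(path, index=False)


def clinical_frame(records: Iterable[ClinicalRecord]) -> pd.DataFrame:
    """Clinical records as a DataFrame indexed by sample id."""
    rows = [
        {
            "sample_id": r.sample_id,
            "patient_id": r.patient_id,
            "tissue_group": r.tissue_group,
            "recurrence": r.recurrence,
            "rfs_days": np.nan if r.rfs_days is None else r.rfs_days,
            "os_days": np.nan if r.os_days is None else r.os_days,
            "dead": r.dead,
        }
        for r in records
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def convert_scale(values, to: str, current: str = "fraction"):
    """Convert methylation values between the fraction and percent scales.

    Idempotent when ``current == to``; works on scalars, arrays, Series,
    DataFrames.
    """
    for scale in (to, current):
        if scale not in ("fraction", "percent"):
            raise ValueError(f"unknown scale {scale!r}")
    if to == current:
        return values
    factor = 100.0 if to == "percent" else 0.01
    if isinstance(values, (pd.DataFrame, pd.Series)):
        return values * factor
    return np.asarray(values, dtype=float) * factor if np.ndim(values) else float(values) * factor


# Columns formatted as percents (1 decimal) in results tables; other floats
# use 4 decimals (probabilities, betas, AUCs).
_PERCENT_COLUMNS = {
    "cutoff_percent",
    "sensitivity_pct",
    "specificity_pct",
    "incidence_pct",
    "call_percent",
    "percent",
}


def write_results_table(records, path: Union[str, Path]) -> None:
    """Write a homogeneous record set as a TSV with deterministic formatting."""
    if isinstance(records, pd.DataFrame):
        frame = records.reset_index() if records.index.name else records
    else:
        records = list(records)
        frame = pd.DataFrame([r if isinstance(r, dict) else vars(r) for r in records])
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, frame.columns)) + "\n")
        for _, row in frame.iterrows():
            cells = []
            for col in frame.columns:
                v = row[col]
                if isinstance(v, float) and np.isnan(v):
                    cells.append("NA")
                elif isinstance(v, (float, np.floating)):
                    fmt = "%.1f" if col in _PERCENT_COLUMNS else "%.4f"
                    cells.append(fmt % v)
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")
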