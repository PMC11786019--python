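"""Readers, writers and run configuration.

The canonical interchange format is comma-delimited UTF-8 text with "."
decimals: the study's data are tabular drug-monitoring and clinical records.
Genotypes may additionally be read from a VCF restricted to the candidate
sites.  Every run can serialize its resolved configuration (YAML) next to
its outputs so results are reproducible from the written artifacts alone.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import SNP_PANEL
from .exceptions import InvalidInputError, RowValidationError, SchemaError
from .mapfit import ConcentrationSample

CONCENTRATION_COLUMNS = ["patient_id", "course", "dose_g_m2", "time_h", "conc_um", "blq_flag"]


def read_concentrations(path) -> pd.DataFrame:
    """Read the long-format plasma-level table.

    Validates the schema (all of ``patient_id, course, dose_g_m2, time_h,
    conc_um, blq_flag``) and every row (positive time, non-negative
    concentration, course >= 1); row failures are collected with their line
    numbers and raised together as :class:`RowValidationError`.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CONCENTRATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"concentration table {path} is missing column(s): {missing}")
    errors = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if not np.isfinite(row["time_h"]) or row["time_h"] <= 0:
            errors.append((line, f"non-positive time_h {row['time_h']}"))
        if not np.isfinite(row["conc_um"]) or row["conc_um"] < 0:
            errors.append((line, f"negative concentration {row['conc_um']}"))
        if row["course"] < 1 or int(row["course"]) != row["course"]:
            errors.append((line, f"invalid course index {row['course']}"))
        if not np.isfinite(row["dose_g_m2"]) or row["dose_g_m2"] <= 0:
            errors.append((line, f"non-positive dose {row['dose_g_m2']}"))
    if errors:
        raise RowValidationError(errors)
    df = df.astype(
        {"patient_id": str, "course": int, "dose_g_m2": float, "time_h": float,
         "conc_um": float, "blq_flag": bool}
    )
    return df[CONCENTRATION_COLUMNS]


def write_concentrations(df: pd.DataFrame, path) -> None:
    # repr round-trips doubles exactly, so read(write(x)) == x
    df[CONCENTRATION_COLUMNS].to_csv(
        path, index=False, float_format=lambda v: repr(float(v))
    )


def samples_from_frame(df: pd.DataFrame) -> list:
    """Convert validated rows (one patient-course) into ConcentrationSample."""
    return [
        ConcentrationSample(
            course=int(r.course), time_h=float(r.time_h),
            conc_um=float(r.conc_um), blq=bool(r.blq_flag),
        )
        for r in df.itertuples()
    ]


#: Allele-pair genotype symbols are normalized against the declared minor
#: allele per SNP (orientation in public reports is inconsistent, so the
#: declaration is explicit rather than inferred).
def _code_genotype(value, snp: str, minor: str, major: str):
    s = str(value).strip().upper().replace("/", "").replace("|", "")
    if s in ("0", "1", "2"):
        return int(s)
    if len(s) == 2 and all(ch in (minor, major) for ch in s):
        return sum(1 for ch in s if ch == minor)
    raise InvalidInputError(
        f"unknown genotype symbol {value!r} for {snp} (alleles {major}/{minor})"
    )


def read_genotypes(path, panel: dict | None = None) -> pd.DataFrame:
    """Read a delimited genotype table into minor-allele counts.

    Expects ``patient_id`` plus one column per SNP holding either allele
    pairs ("CT") or counts (0/1/2).  Columns for SNPs not in the panel are
    kept but flagged with a warning.
    """
    import warnings

    panel = panel or SNP_PANEL
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise SchemaError(f"genotype table {path} is missing column 'patient_id'")
    out = pd.DataFrame({"patient_id": df["patient_id"].astype(str)})
    errors = []
    for col in df.columns:
        if col == "patient_id":
            continue
        if col not in panel:
            warnings.warn(f"genotype column {col!r} is not a declared SNP; skipped",
                          stacklevel=2)
            continue
        minor, major = panel[col]["minor"], panel[col]["major"]
        coded = []
        for idx, value in df[col].items():
            try:
                coded.append(_code_genotype(value, col, minor, major))
            except InvalidInputError as err:
                errors.append((idx + 2, str(err)))
                coded.append(-1)
        out[col] = coded
    if errors:
        raise RowValidationError(errors)
    return out


def read_genotypes_vcf(path, panel: dict | None = None) -> pd.DataFrame:
    """Read genotypes for the candidate sites from a VCF.

    Counts are oriented to the declared minor allele: if ALT is the minor
    allele the ALT count is used, if REF is minor the count is inverted.
    """
    from cyvcf2 import VCF

    panel = panel or SNP_PANEL
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    data = {"patient_id": sample_ids}
    for record in vcf:
        rsid = record.ID
        if rsid not in panel:
            continue
        minor, major = panel[rsid]["minor"], panel[rsid]["major"]
        alt = record.ALT[0] if record.ALT else None
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (cyvcf2 with gts012=False uses 3)
        alt_counts = [sum(1 for a in gt[:2] if a == 1) for gt in record.genotypes]
        if alt == minor and record.REF == major:
            counts = alt_counts
        elif alt == major and record.REF == minor:
            counts = [2 - c for c in alt_counts]
        else:
            raise InvalidInputError(
                f"VCF alleles {record.REF}>{alt} at {rsid} do not match the "
                f"declared {major}/{minor}"
            )
        data[rsid] = counts
    vcf.close()
    return pd.DataFrame(data)


@dataclass
class RunConfig:
    """Resolved pipeline configuration, fully serializable to YAML."""

    seed: int = 0
    out_dir: str = "results"
    prior_overrides: dict = field(default_factory=dict)
    error_cv: float = 0.10
    error_floor_um: float = 0.05
    genetic_models: dict = field(default_factory=lambda: {"toxicity": "dominant",
                                                          "relapse": "dominant",
                                                          "pk": "recessive"})
    age_cutoff: float = 10.0  # children vs adolescents split
    multiplicity_method: str = "bonferroni"
    multiplicity_m: int | None = None
    alpha: float = 0.05

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        """Short stable hash of the resolved configuration."""
        canonical = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
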