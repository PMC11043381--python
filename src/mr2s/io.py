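"""Reading and writing GWAS summary-statistic tables and study manifests.

Tables are tab-separated text with a header row.  The canonical column set
is ``SNP CHR POS EA OA EAF BETA SE P N``; a schema mapping lets callers
rename columns, since public GWAS exports use heterogeneous headers.
Missing effect-allele frequency is written and read as the sentinel "NA".
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from .audit import AuditLog
from .types import (
    StudyManifest,
    StudyMeta,
    SummaryStatRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

_FIELD_FOR_COLUMN = {
    "SNP": "snp_id",
    "CHR": "chrom",
    "POS": "pos",
    "EA": "effect_allele",
    "OA": "other_allele",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "pval",
    "N": "n",
}


def read_sumstats(
    path,
    schema: Optional[Mapping[str, str]] = None,
    audit: Optional[AuditLog] = None,
    sep: str = "\t",
) -> list[SummaryStatRecord]:
    """Read a summary-statistic table, validating each row.

    ``schema`` maps canonical names to the file's actual headers, e.g.
    ``{"SNP": "rsid", "P": "pvalue"}``.  Rows violating a hard invariant
    (degenerate alleles, nonpositive se, ...) are dropped with a logged
    reason; a p-value inconsistent with beta/se only warns, because
    published GWAS round p-values.

    Raises ``ValidationError`` if the file is empty or a mandatory column
    is missing.
    """
    schema = dict(schema or {})
    rename = {schema.get(c, c): c for c in CANONICAL_COLUMNS}
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty summary-statistic file") from None
    if df.empty:
        raise ValidationError(f"{path}: summary-statistic file has no data rows")
    df = df.rename(columns=rename)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns and c != "EAF"]
    if missing:
        raise ValidationError(f"{path}: missing mandatory column(s) {missing}")
    has_eaf = "EAF" in df.columns

    records: list[SummaryStatRecord] = []
    for _, row in df.iterrows():
        snp_id = str(row["SNP"])
        try:
            eaf = None
            if has_eaf:
                raw = row["EAF"]
                if not (pd.isna(raw) or str(raw).upper() in ("NA", "NAN", "")):
                    eaf = float(raw)
            rec = SummaryStatRecord(
                snp_id=snp_id,
                chrom=str(row["CHR"]),
                pos=int(float(row["POS"])),
                effect_allele=str(row["EA"]).upper(),
                other_allele=str(row["OA"]).upper(),
                eaf=eaf,
                beta=float(row["BETA"]),
                se=float(row["SE"]),
                pval=float(row["P"]),
                n=float(row["N"]),
            )
            rec.validate()
        except ValidationError as exc:
            reason = _short_reason(str(exc))
            if audit is not None:
                audit.record(snp_id, "read_sumstats", "drop", reason)
            logger.warning("dropping %s: %s", snp_id, reason)
            continue
        except (TypeError, ValueError) as exc:
            if audit is not None:
                audit.record(snp_id, "read_sumstats", "drop", "unparseable row")
            logger.warning("dropping %s: unparseable row (%s)", snp_id, exc)
            continue
        if not rec.pval_consistent():
            if audit is not None:
                audit.record(snp_id, "read_sumstats", "warn", "pval inconsistent with beta/se")
            logger.warning("%s: p-value inconsistent with beta/se", snp_id)
        if audit is not None:
            audit.record(snp_id, "read_sumstats", "keep", "")
        records.append(rec)
    return records


def _short_reason(message: str) -> str:
    # messages are "<snp>: <reason>"; keep the reason part
    return message.split(": ", 1)[-1]


def write_sumstats(records: list[SummaryStatRecord], path) -> None:
    """Write records as canonical TSV; round-trips at full precision."""
    if not records:
        raise ValidationError("refusing to write an empty summary-statistic file")
    rows = []
    for r in records:
        rows.append(
            {
                "SNP": r.snp_id,
                "CHR": r.chrom,
                "POS": r.pos,
                "EA": r.effect_allele,
                "OA": r.other_allele,
                "EAF": "NA" if r.eaf is None else repr(r.eaf),
                "BETA": repr(r.beta),
                "SE": repr(r.se),
                "P": repr(r.pval),
                "N": repr(r.n),
            }
        )
    pd.DataFrame(rows, columns=CANONICAL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ld_matrix(path) -> pd.DataFrame:
    """Read a square r-squared matrix (TSV, SNP IDs as header and index)."""
    ld = pd.read_csv(path, sep="\t", index_col=0)
    ld.index = ld.index.astype(str)
    ld.columns = ld.columns.astype(str)
    return ld


def write_ld_matrix(ld: pd.DataFrame, path) -> None:
    ld.to_csv(path, sep="\t")


def _parse_study(entry: dict, base: Path) -> tuple[StudyMeta, str]:
    meta = StudyMeta(
        trait_name=entry["name"],
        trait_type=entry.get("type", "quantitative"),
        n_total=int(entry["n_total"]),
        n_cases=int(entry["n_cases"]) if "n_cases" in entry else None,
        n_controls=int(entry["n_controls"]) if "n_controls" in entry else None,
        source_label=entry.get("source", ""),
    )
    meta.validate()
    file_path = str((base / entry["file"]).resolve()) if not Path(entry["file"]).is_absolute() else entry["file"]
    return meta, file_path


def load_manifest(path) -> StudyManifest:
    """Load a YAML/JSON study manifest.

    Keys: ``exposures`` and ``outcomes`` (lists of ``{name, type, n_total,
    [n_cases, n_controls], file, [source]}``), optional ``pairs`` (list of
    ``[exposure_name, outcome_name]``; defaults to the full grid) and
    optional ``n_exposure_traits`` (defaults to the number of exposures;
    used for the Bonferroni correction).

    Every referenced file must exist.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = path.parent
    exposures = [_parse_study(e, base) for e in cfg.get("exposures", [])]
    outcomes = [_parse_study(e, base) for e in cfg.get("outcomes", [])]
    dangling = [f for _, f in exposures + outcomes if not Path(f).exists()]
    if dangling:
        raise ValidationError(f"manifest references missing file(s): {dangling}")
    if "pairs" in cfg and cfg["pairs"]:
        pairs = [(str(a), str(b)) for a, b in cfg["pairs"]]
        known_e = {m.trait_name for m, _ in exposures}
        known_o = {m.trait_name for m, _ in outcomes}
        for a, b in pairs:
            if a not in known_e or b not in known_o:
                raise ValidationError(f"pair ({a}, {b}) names an unknown study")
    else:
        pairs = [
            (e.trait_name, o.trait_name)
            for e, _ in exposures
            for o, _ in outcomes
        ]
    manifest = StudyManifest(
        exposures=exposures,
        outcomes=outcomes,
        pairs=pairs,
        n_exposure_traits=int(cfg.get("n_exposure_traits", len(exposures))),
    )
    manifest.validate()
    return manifest
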