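"""Peak-list and PSM-table readers/writers and the Percolator-input exporter.

MGF is the only peak-list format (self-contained text; NCE and analyzer ride
in TITLE ``key=value`` tokens because MGF has no standard slot for them).
PSM tables are tab-separated with a header; scan numbers are 1-based and
retention times are minutes.  Every reader logs input/retained/excluded
counts at INFO.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .chem import MAX_LENGTH, MAX_PRECURSOR_CHARGE, MIN_LENGTH, Peptide

logger = logging.getLogger(__name__)


@dataclass
class RawSpectrum:
    """One MS2 spectrum: sorted peak arrays plus acquisition metadata."""

    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float
    precursor_charge: int | None
    rt_minutes: float = 0.0
    nce: float = 30.0
    analyzer: str = "FTMS"
    scan: int = 0
    rawfile: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if self.mz.size > 1 and np.any(np.diff(self.mz) <= 0):
            # merge exact duplicates rather than reject
            uniq, inv = np.unique(self.mz, return_inverse=True)
            summed = np.zeros_like(uniq)
            np.add.at(summed, inv, self.intensity)
            self.mz, self.intensity = uniq, summed


@dataclass(frozen=True)
class PSMRecord:
    """One spectrum<->peptide assignment from a search engine."""

    rawfile: str
    scan: int
    peptide: Peptide
    engine: str = "generic"
    engine_score: float = 0.0
    is_decoy: bool = False
    retention_time: float = 0.0
    rank: int = 1

    def key(self) -> tuple:
        return (self.rawfile, self.scan, self.peptide.modified_sequence,
                self.peptide.precursor_charge, self.engine)


@dataclass
class FilterStats:
    """Bookkeeping for row filtering: input = retained + excluded, always."""

    n_input: int = 0
    n_retained: int = 0
    excluded: dict[str, int] = field(default_factory=dict)

    def exclude(self, reason: str) -> None:
        self.excluded[reason] = self.excluded.get(reason, 0) + 1

    @property
    def n_excluded(self) -> int:
        return sum(self.excluded.values())


def _make_title(spectrum: RawSpectrum) -> str:
    return (f"{spectrum.rawfile}.{spectrum.scan} rawfile={spectrum.rawfile} "
            f"scan={spectrum.scan} nce={spectrum.nce:g} analyzer={spectrum.analyzer}")


def _parse_title(title: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for token in title.split():
        if "=" in token:
            key, _, value = token.partition("=")
            out[key] = value
    return out


def _check_mgf_nesting(path: str) -> None:
    """Validate BEGIN IONS / END IONS pairing, reporting the offending line."""
    depth = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip().upper()
            if stripped == "BEGIN IONS":
                depth += 1
                if depth > 1:
                    raise ValueError(f"{path}:{lineno}: nested BEGIN IONS")
            elif stripped == "END IONS":
                depth -= 1
                if depth < 0:
                    raise ValueError(f"{path}:{lineno}: END IONS without BEGIN IONS")
    if depth != 0:
        raise ValueError(f"{path}: BEGIN IONS without matching END IONS")


def read_mgf(path: str) -> list[RawSpectrum]:
    """Read an MGF peak list; blocks missing CHARGE are kept but flagged."""
    _check_mgf_nesting(path)
    spectra: list[RawSpectrum] = []
    n_flagged = 0
    with _mgf.MGF(str(path)) as reader:
        for block in reader:
            params = block.get("params", {})
            title = params.get("title", "")
            meta = _parse_title(title)
            charge_param = params.get("charge")
            if charge_param:
                charge: int | None = int(charge_param[0])
            else:
                charge = None
                n_flagged += 1
                logger.warning("MGF block %r missing CHARGE; charge set unknown", title)
            pepmass = params.get("pepmass", (0.0,))
            rt = float(params.get("rtinseconds", 0.0)) / 60.0
            spectra.append(RawSpectrum(
                mz=block.get("m/z array", np.empty(0)),
                intensity=block.get("intensity array", np.empty(0)),
                precursor_mz=float(pepmass[0]) if pepmass[0] is not None else 0.0,
                precursor_charge=charge,
                rt_minutes=rt,
                nce=float(meta.get("nce", 30.0)),
                analyzer=meta.get("analyzer", "FTMS"),
                scan=int(meta.get("scan", len(spectra) + 1)),
                rawfile=meta.get("rawfile", ""),
            ))
    logger.info("read_mgf(%s): %d spectra, %d missing CHARGE", path, len(spectra), n_flagged)
    return spectra


def write_mgf(spectra: list[RawSpectrum], path: str) -> None:
    entries = []
    for s in spectra:
        params = {
            "title": _make_title(s),
            "pepmass": s.precursor_mz,
            "rtinseconds": s.rt_minutes * 60.0,
        }
        if s.precursor_charge is not None:
            params["charge"] = s.precursor_charge
        entries.append({"m/z array": s.mz, "intensity array": s.intensity,
                        "params": params})
    _mgf.write(entries, str(path), file_mode="w")


_GENERIC_COLUMNS = {
    "rawfile": "rawfile", "scan": "scan", "modified_sequence": "modified_sequence",
    "precursor_charge": "precursor_charge", "engine_score": "engine_score",
}
_MAXQUANT_COLUMNS = {
    "Raw file": "rawfile", "Scan number": "scan",
    "Modified sequence": "modified_sequence", "Charge": "precursor_charge",
    "Score": "engine_score",
}


def read_psm_table(path: str, dialect: str = "generic",
                   engine: str | None = None) -> tuple[list[PSMRecord], FilterStats]:
    """Read a tab-separated PSM table.

    Rows outside the identification domain (length 7-30, precursor charge <7)
    are excluded and counted, never silently dropped.  The decoy flag comes
    from an ``is_decoy`` label column or a MaxQuant-style ``Reverse`` column.
    """
    if dialect == "generic":
        colmap = _GENERIC_COLUMNS
    elif dialect == "maxquant-like":
        colmap = _MAXQUANT_COLUMNS
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in colmap if c not in table.columns]
    if missing:
        raise ValueError(f"PSM table {path} is missing mandatory column(s): {missing}")
    table = table.rename(columns=colmap)

    stats = FilterStats(n_input=len(table))
    records: list[PSMRecord] = []
    for _, row in table.iterrows():
        charge = int(row["precursor_charge"])
        if charge >= MAX_PRECURSOR_CHARGE + 1 or charge < 1:
            stats.exclude("charge outside 1-6")
            continue
        modseq = str(row["modified_sequence"])
        if dialect == "maxquant-like":
            modseq = (modseq.strip("_")
                      .replace("(Oxidation (M))", "(ox)")
                      .replace("(Carbamidomethyl (C))", "(cam)"))
        try:
            peptide = Peptide.from_modified_sequence(modseq, precursor_charge=charge)
        except ValueError as err:
            if "length" in str(err):
                stats.exclude("length outside 7-30")
            else:
                stats.exclude("unparseable sequence")
            continue
        if "is_decoy" in row.index:
            is_decoy = bool(row["is_decoy"]) and str(row["is_decoy"]).lower() not in ("false", "0", "")
        elif "Reverse" in row.index:
            is_decoy = str(row["Reverse"]) == "+"
        else:
            is_decoy = modseq.startswith("REV_")
        records.append(PSMRecord(
            rawfile=str(row["rawfile"]), scan=int(row["scan"]), peptide=peptide,
            engine=engine or str(row.get("engine", "generic")),
            engine_score=float(row["engine_score"]), is_decoy=is_decoy,
            retention_time=float(row.get("retention_time", 0.0)),
            rank=int(row.get("rank", 1)),
        ))
    stats.n_retained = len(records)
    assert stats.n_retained + stats.n_excluded == stats.n_input
    logger.info("read_psm_table(%s): %d input, %d retained, %d excluded %s",
                path, stats.n_input, stats.n_retained, stats.n_excluded, stats.excluded)
    return records, stats


def write_psm_table(records: list[PSMRecord], path: str) -> None:
    rows = [{
        "rawfile": r.rawfile, "scan": r.scan,
        "modified_sequence": r.peptide.modified_sequence,
        "precursor_charge": r.peptide.precursor_charge, "engine": r.engine,
        "engine_score": r.engine_score, "is_decoy": r.is_decoy,
        "retention_time": r.retention_time, "rank": r.rank,
    } for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_pin(psms: list[PSMRecord], features: pd.DataFrame, path: str) -> None:
    """Write a Percolator-input (PIN) file.

    Columns: SpecId, Label (+1/-1), ScanNr, <features...>, Peptide, Proteins.
    Row order is deterministic: (rawfile, scan, peptide).
    """
    if len(psms) != len(features):
        raise ValueError("one feature vector per PSM required")
    values = features.to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-finite feature {features.columns[j]!r} for PSM "
            f"{psms[int(i)].rawfile}:{psms[int(i)].scan} "
            f"{psms[int(i)].peptide.modified_sequence}"
        )
    rows = []
    for psm, feat in zip(psms, features.itertuples(index=False)):
        rows.append({
            "SpecId": f"{psm.rawfile}_{psm.scan}_{psm.peptide.precursor_charge}_{psm.rank}",
            "Label": -1 if psm.is_decoy else 1,
            "ScanNr": psm.scan,
            **{name: getattr(feat, name) for name in features.columns},
            "Peptide": f"-.{psm.peptide.modified_sequence}.-",
            "Proteins": "synthetic",
            "_sort": (psm.rawfile, psm.scan, psm.peptide.modified_sequence),
        })
    frame = pd.DataFrame(rows).sort_values("_sort").drop(columns="_sort")
    frame.to_csv(path, sep="\t", index=False)


__all__ = [
    "RawSpectrum", "PSMRecord", "FilterStats", "read_mgf", "write_mgf",
    "read_psm_table", "write_psm_table", "write_pin", "replace",
]
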