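"""MGF spectrum I/O and the glycopeptide-spectrum-match (GSM) table.

Spectra are centroided CID MS/MS peak lists read from Mascot Generic Format
files (via pyteomics). The GSM table is a TSV linking each spectrum title to
its identified glycopeptide ID, an optional manual fucosylation label
(none / core / outer / dual) and a free-text source tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import pandas as pd
from pyteomics import mgf as _mgf

from .glycan import GlycopeptideID, format_glycopeptide_id, parse_glycopeptide_id

#: Closed vocabulary of fucosylation classes, in fixed encoding order.
CLASS_ORDER: tuple[str, ...] = ("none", "core", "outer", "dual")


class MgfError(ValueError):
    """Raised on structurally invalid MGF input."""


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass
class Spectrum:
    """One centroided MS/MS spectrum. Peaks are kept sorted by m/z."""

    title: str
    precursor_mz: float
    precursor_charge: int | None = None
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted((Peak(float(m), float(i)) for m, i in self.peaks),
                            key=lambda p: (p.mz, p.intensity))

    @property
    def base_peak_intensity(self) -> float:
        return max((p.intensity for p in self.peaks), default=0.0)


@dataclass
class GsmRecord:
    """One glycopeptide-spectrum match: spectrum title, glycopeptide ID,
    optional manual fucosylation label, and sample source."""

    spectrum_title: str
    glycopeptide: GlycopeptideID
    manual_label: str | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.manual_label is not None and self.manual_label not in CLASS_ORDER:
            raise ValueError(
                f"unknown fucosylation label {self.manual_label!r}; "
                f"allowed values: {', '.join(CLASS_ORDER)}"
            )


def _validate_mgf_structure(path: str) -> None:
    # Pre-scan for balanced BEGIN IONS / END IONS and numeric peak lines so
    # errors can name the offending line; pyteomics is lenient about both.
    in_block = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line[0] in "#;!/":
                continue
            if line == "BEGIN IONS":
                if in_block:
                    raise MgfError(f"line {lineno}: BEGIN IONS inside an open block")
                in_block = True
            elif line == "END IONS":
                if not in_block:
                    raise MgfError(f"line {lineno}: END IONS without BEGIN IONS")
                in_block = False
            elif in_block and "=" not in line:
                fields = line.split()
                if len(fields) < 2:
                    raise MgfError(f"line {lineno}: malformed peak line {line!r}")
                try:
                    float(fields[0]), float(fields[1])
                except ValueError:
                    raise MgfError(
                        f"line {lineno}: non-numeric peak line {line!r}"
                    ) from None
    if in_block:
        raise MgfError("unterminated spectrum block: missing END IONS at end of file")


def read_mgf(path: str) -> list[Spectrum]:
    """Read an MGF file into a list of spectra.

    Peaks are sorted ascending by m/z and zero-intensity peaks retained.
    Blank lines and comment lines are ignored. Duplicate titles are an error.
    """
    _validate_mgf_structure(path)
    spectra: list[Spectrum] = []
    seen: set[str] = set()
    with _mgf.read(path, use_index=False) as reader:
        for entry in reader:
            params = entry["params"]
            title = str(params.get("title", ""))
            if title in seen:
                raise MgfError(f"duplicate spectrum title {title!r}")
            seen.add(title)
            pepmass = params.get("pepmass", (0.0,))[0]
            charge_list = params.get("charge")
            charge = int(charge_list[0]) if charge_list else None
            peaks = [Peak(float(m), float(i))
                     for m, i in zip(entry["m/z array"], entry["intensity array"])]
            spectra.append(Spectrum(title, float(pepmass or 0.0), charge, peaks))
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: str) -> None:
    """Write spectra to MGF; round-trips through :func:`read_mgf` at
    5-decimal precision. Spectra with unknown charge get no CHARGE line."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.title}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.5f}\n")
            if s.precursor_charge is not None:
                sign = "+" if s.precursor_charge > 0 else "-"
                fh.write(f"CHARGE={abs(s.precursor_charge)}{sign}\n")
            for p in s.peaks:
                fh.write(f"{p.mz:.5f} {p.intensity:.5f}\n")
            fh.write("END IONS\n")


def read_gsm_table(path: str) -> list[GsmRecord]:
    """Read a GSM TSV with columns ``title``, ``glycopeptide_id`` and
    optional ``label`` and ``source``. Lines starting '#' are comments."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"title", "glycopeptide_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"GSM table missing required column(s): {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        label = getattr(row, "label", None)
        if label is not None and (pd.isna(label) or label == ""):
            label = None
        source = getattr(row, "source", "") or ""
        if pd.isna(source):
            source = ""
        records.append(
            GsmRecord(
                spectrum_title=row.title,
                glycopeptide=parse_glycopeptide_id(row.glycopeptide_id),
                manual_label=label,
                source=source,
            )
        )
    return records


def write_gsm_table(records: Sequence[GsmRecord], path: str,
                    header_lines: Sequence[str] = ()) -> None:
    """Write GSM records as TSV; ``header_lines`` become '#' comments."""
    df = pd.DataFrame(
        {
            "title": [r.spectrum_title for r in records],
            "glycopeptide_id": [format_glycopeptide_id(r.glycopeptide) for r in records],
            "label": [r.manual_label or "" for r in records],
            "source": [r.source for r in records],
        }
    )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
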