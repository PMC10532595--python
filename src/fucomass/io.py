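"""Peak-list, MGF and report plumbing.

Peak lists travel as CSV/TSV tables with columns ``mz, intensity[,
charge]`` or as MGF files (read through :mod:`pyteomics.mgf`).  Assignment
and annotation results are written as TSV/JSON tables mirroring the
two-column *m/z* / composition layout of published oligosaccharide
tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from pyteomics import mgf as _mgf

from .annotate import AnnotatedSpectrum
from .assign import Assignment, Peak
from .notation import render_ion_notation

__all__ = [
    "read_peaks",
    "write_peaks",
    "read_mgf",
    "write_mgf",
    "assignments_frame",
    "write_assignments",
    "annotation_report",
    "write_annotation_report",
]


def read_peaks(path: str | Path) -> list[Peak]:
    """Read a CSV/TSV peak list (columns mz, intensity[, charge])."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    if "mz" not in df.columns:
        raise ValueError(f"{path}: missing required column 'mz'")
    peaks = []
    for _, row in df.iterrows():
        charge = row.get("charge")
        charge = int(charge) if pd.notna(charge) else None
        intensity = row.get("intensity")
        intensity = float(intensity) if pd.notna(intensity) else 0.0
        peaks.append(Peak(mz=float(row["mz"]), intensity=intensity, charge=charge))
    return peaks


def write_peaks(peaks: list[Peak], path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    pd.DataFrame(
        {
            "mz": [p.mz for p in peaks],
            "intensity": [p.intensity for p in peaks],
            "charge": [p.charge for p in peaks],
        }
    ).to_csv(path, sep=sep, index=False)


def read_mgf(path: str | Path) -> dict[str, dict]:
    """Read MGF ION blocks into {title: {'peaks': [...], 'pepmass', 'charge'}}."""
    out: dict[str, dict] = {}
    with _mgf.MGF(str(path)) as reader:
        for i, spec in enumerate(reader):
            params = spec.get("params", {})
            title = str(params.get("title", f"spectrum_{i}"))
            charges = params.get("charge")
            charge = abs(int(charges[0])) if charges else None
            peaks = [
                Peak(mz=float(m), intensity=float(it), charge=None)
                for m, it in zip(spec["m/z array"], spec["intensity array"])
            ]
            pepmass = params.get("pepmass", (None,))[0]
            out[title] = {"peaks": peaks, "pepmass": pepmass, "charge": charge}
    return out


def write_mgf(
    spectra: dict[str, dict], path: str | Path
) -> None:
    """Write {title: {'peaks', 'pepmass', 'charge'}} blocks as MGF."""
    entries = []
    for title, spec in spectra.items():
        params = {"title": title}
        if spec.get("pepmass") is not None:
            params["pepmass"] = spec["pepmass"]
        if spec.get("charge") is not None:
            params["charge"] = [-int(spec["charge"])]
        peaks = spec["peaks"]
        entries.append(
            {
                "params": params,
                "m/z array": [p.mz for p in peaks],
                "intensity array": [p.intensity for p in peaks],
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def assignments_frame(assignments: list[list[Assignment]]) -> pd.DataFrame:
    """Flatten per-peak assignment lists into a tidy table."""
    rows = []
    for hits in assignments:
        if not hits:
            continue
        for rank, a in enumerate(hits, start=1):
            comp = a.ion.composition
            rows.append(
                {
                    "mz_observed": a.peak.mz,
                    "intensity": a.peak.intensity,
                    "composition": render_ion_notation(a.ion),
                    "charge": a.ion.charge,
                    "mz_theoretical": a.peak.mz - a.delta,
                    "delta_mDa": 1000.0 * a.delta,
                    "rank": rank,
                    "labeled": comp.labeled,
                    "water_loss": comp.extra_water_loss,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "mz_observed", "intensity", "composition", "charge",
            "mz_theoretical", "delta_mDa", "rank", "labeled", "water_loss",
        ],
    )


def write_assignments(
    assignments: list[list[Assignment]], path: str | Path
) -> None:
    path = Path(path)
    frame = assignments_frame(assignments)
    if path.suffix.lower() == ".json":
        path.write_text(frame.to_json(orient="records", indent=2))
    else:
        frame.to_csv(path, sep="\t", index=False, float_format="%.4f")


def annotation_report(annotated: AnnotatedSpectrum) -> dict:
    """JSON-serializable annotation report for one candidate."""
    return {
        "candidate": annotated.candidate.render(),
        "precursor": render_ion_notation(annotated.precursor),
        "score": round(annotated.score, 4),
        "unexplained_fraction": round(annotated.unexplained_fraction, 4),
        "n_peaks": len(annotated.peaks),
        "matches": [
            {
                "mz_observed": m.peak.mz,
                "kind": m.fragment.kind,
                "index": m.fragment.index,
                "cleavage": m.fragment.cleavage,
                "charge": m.charge,
                "mz_theoretical": round(m.mz_theoretical, 4),
                "delta_mDa": round(1000.0 * m.delta, 2),
                "label_retained": m.fragment.label_retained,
            }
            for m in annotated.matches
        ],
    }


def write_annotation_report(
    annotated: AnnotatedSpectrum, path: str | Path
) -> None:
    Path(path).write_text(json.dumps(annotation_report(annotated), indent=2))


def annotation_text_table(annotated: AnnotatedSpectrum) -> str:
    """Human-readable fixed-width annotation table."""
    lines = [
        f"candidate: {annotated.candidate.render()}",
        f"precursor: {render_ion_notation(annotated.precursor)}",
        f"score: {annotated.score:.3f}   "
        f"unexplained: {annotated.unexplained_fraction:.3f}",
        f"{'m/z obs':>10} {'frag':>8} {'z':>2} {'m/z calc':>10} {'d(mDa)':>7}",
    ]
    for m in annotated.matches:
        name = f"{m.fragment.kind}{m.fragment.index}"
        if m.fragment.ring_pair:
            i, j = m.fragment.ring_pair
            name = f"{i},{j}-{name}"
        lines.append(
            f"{m.peak.mz:>10.4f} {name:>8} {m.charge:>2} "
            f"{m.mz_theoretical:>10.4f} {1000 * m.delta:>7.2f}"
        )
    return "\n".join(lines)
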