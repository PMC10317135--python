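"""Local batch pipeline: zip work units, CSV results, score import.

Mirrors the production data flow on one machine: well images are packed
into zip archives (the work units a worker pulls), each archive is
scored synchronously, results are finalized into a CSV, and the CSV is
imported into an embedded relational score table (sqlite).  Manual
scores are sacrosanct: an automatic record is only inserted where no
manual record exists for the same well and inspection, never replacing
anything, and automatic records carry the inspection time as their
score time so they can always be told apart and superseded.
"""

from __future__ import annotations

import csv
import fnmatch
import logging
import sqlite3
import zipfile
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

from .scoring import WellScore

log = logging.getLogger("artscore.pipeline")

CSV_COLUMNS = (
    "well_id", "score", "probability", "x0", "y0", "inspection_time", "source"
)


@dataclass(frozen=True)
class ScoreRecord:
    well_id: str
    score_no: int | None
    source: str  # "manual" | "ARTscore"
    score_time: str  # ISO timestamp
    inspection_time: str

    def __post_init__(self) -> None:
        if self.source == "ARTscore" and self.score_time != self.inspection_time:
            raise ValueError(
                "automatic records are dated to their inspection time"
            )


# ---------------------------------------------------------------------
# work packaging
# ---------------------------------------------------------------------

def package_work(
    image_dir: str | Path,
    patterns: list[str] | None = None,
    batch_size: int = 50,
    out_dir: str | Path | None = None,
    exclude: list[str] | None = None,
) -> tuple[list[Path], dict[str, list[str]]]:
    """Pack matching images into zip archives of at most ``batch_size``.

    Returns the archive paths and a manifest mapping archive name to
    the well image files it holds.  An empty match set raises.
    """
    image_dir = Path(image_dir)
    patterns = patterns or ["*.png", "*.tif", "*.tiff"]
    files = sorted(
        p for p in image_dir.iterdir()
        if p.is_file()
        and any(fnmatch.fnmatch(p.name, pat) for pat in patterns)
        and not any(fnmatch.fnmatch(p.name, pat) for pat in (exclude or []))
    )
    if not files:
        raise FileNotFoundError(
            f"no images matching {patterns} under {image_dir}"
        )
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    out = Path(out_dir) if out_dir else image_dir / "work"
    out.mkdir(parents=True, exist_ok=True)
    archives: list[Path] = []
    manifest: dict[str, list[str]] = {}
    for b, i in enumerate(range(0, len(files), batch_size)):
        chunk = files[i : i + batch_size]
        arc = out / f"work_{b:04d}.zip"
        with zipfile.ZipFile(arc, "w", zipfile.ZIP_DEFLATED) as zf:
            for f in chunk:
                zf.write(f, arcname=f.name)
        archives.append(arc)
        manifest[arc.name] = [f.name for f in chunk]
        log.info("packed %s: %d images", arc.name, len(chunk))
    return archives, manifest


def unpack_work(archive: str | Path, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with zipfile.ZipFile(archive) as zf:
        zf.extractall(out)
        return [out / n for n in zf.namelist()]


# ---------------------------------------------------------------------
# CSV finalizer
# ---------------------------------------------------------------------

def finalize_csv(well_scores: list[WellScore], out_path: str | Path) -> Path:
    """One row per well, UNSCORED wells included; append-safe."""
    out = Path(out_path)
    new_file = not out.exists()
    with open(out, "a", newline="") as f:
        writer = csv.writer(f)
        if new_file:
            writer.writerow(CSV_COLUMNS)
        for ws in well_scores:
            top = ws.top_chops[0] if ws.top_chops else None
            writer.writerow([
                ws.well_id,
                ws.score_no if ws.scored else "UNSCORED",
                f"{ws.probability:.4f}" if ws.probability is not None else "",
                top.window.x0 if top else "",
                top.window.y0 if top else "",
                ws.inspection_time.isoformat(),
                ws.source,
            ])
    return out


def read_csv(path: str | Path) -> list[dict]:
    with open(path, newline="") as f:
        return list(csv.DictReader(f))


# ---------------------------------------------------------------------
# score table
# ---------------------------------------------------------------------

class ScoreTable:
    """Embedded score store with the manual-precedence import policy."""

    def __init__(self, path: str | Path = ":memory:"):
        self.conn = sqlite3.connect(str(path))
        self.conn.execute(
            """CREATE TABLE IF NOT EXISTS scores (
                   well_id TEXT NOT NULL,
                   score_no INTEGER,
                   source TEXT NOT NULL,
                   score_time TEXT NOT NULL,
                   inspection_time TEXT NOT NULL,
                   UNIQUE (well_id, inspection_time, source)
               )"""
        )
        self.conn.commit()

    def add_manual(
        self, well_id: str, score_no: int, inspection_time: str,
        score_time: str | None = None,
    ) -> None:
        self.conn.execute(
            "INSERT INTO scores VALUES (?,?,?,?,?)",
            (well_id, score_no, "manual",
             score_time or datetime.now(timezone.utc).isoformat(),
             inspection_time),
        )
        self.conn.commit()

    def records(self, source: str | None = None) -> list[ScoreRecord]:
        q = "SELECT well_id, score_no, source, score_time, inspection_time FROM scores"
        args: tuple = ()
        if source:
            q += " WHERE source = ?"
            args = (source,)
        return [
            ScoreRecord(*row) for row in self.conn.execute(q + " ORDER BY rowid", args)
        ]

    def manual_fingerprint(self) -> tuple:
        """Hashable snapshot of all manual records (for invariants)."""
        return tuple(sorted(
            (r.well_id, r.score_no, r.score_time, r.inspection_time)
            for r in self.records("manual")
        ))

    def _exists(self, well_id: str, inspection_time: str, source: str) -> bool:
        cur = self.conn.execute(
            "SELECT 1 FROM scores WHERE well_id=? AND inspection_time=? AND source=?",
            (well_id, inspection_time, source),
        )
        return cur.fetchone() is not None

    def close(self) -> None:
        self.conn.close()


@dataclass
class ImportReport:
    inserted: int = 0
    skipped_manual: int = 0
    skipped_duplicate: int = 0
    rejected_rows: int = 0


def import_scores(csv_path: str | Path, table: ScoreTable) -> ImportReport:
    """Import a finalizer CSV into the score table.

    Automatic records are inserted only where no manual record exists
    for the same (well, inspection); manual records are never modified.
    Re-importing the same CSV inserts nothing (idempotent).  Malformed
    rows are rejected, logged and skipped.
    """
    report = ImportReport()
    for row in read_csv(csv_path):
        try:
            well_id = row["well_id"]
            inspection = row["inspection_time"]
            raw = row["score"]
            score = None if raw.upper() == "UNSCORED" else int(raw)
            if not well_id or not inspection:
                raise ValueError("missing well id or inspection time")
        except (KeyError, ValueError, AttributeError) as err:
            log.warning("rejected row %r: %s", row, err)
            report.rejected_rows += 1
            continue
        if table._exists(well_id, inspection, "manual"):
            report.skipped_manual += 1
            continue
        if table._exists(well_id, inspection, "ARTscore"):
            report.skipped_duplicate += 1
            continue
        # automatic scores carry the inspection time as score time, so a
        # later manual rating is always the newer record
        table.conn.execute(
            "INSERT INTO scores VALUES (?,?,?,?,?)",
            (well_id, score, "ARTscore", inspection, inspection),
        )
        report.inserted += 1
    table.conn.commit()
    return report
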