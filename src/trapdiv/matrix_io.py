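"""Band-matrix data model, CSV input/output, and the packaged reference panel.

The whole pipeline consumes a single object, :class:`MarkerMatrix`: a binary
strains x bands table in which every band (electrophoretic fragment position)
belongs to exactly one primer combination. Dominant markers are scored
present (1) or absent (0); missing scores are a data error, not a value.

File dialect
------------
Comma-separated UTF-8. The header row is ``strain`` followed by one token per
band, formatted ``<primer_combination>:<band_label>[:<size_bp>]`` — the band
token carries the primer grouping so matrix and grouping travel in one flat
file. Each body row is a strain id followed by 0/1 cells.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from trapdiv.errors import ValidationError

#: Grand total of scorable fragments as printed in the source panel's running
#: text. Kept as metadata only: the panel's per-primer band counts sum to 288.
PRINTED_TOTAL_FRAGMENTS = 287


@dataclass(frozen=True)
class BandDef:
    """One scored band: its primer combination, label, and optional size in bp."""

    primer_combination: str
    band_label: str
    size_bp: int | None = None

    def __post_init__(self) -> None:
        if not self.primer_combination:
            raise ValidationError("primer_combination must be non-empty")
        if not self.band_label:
            raise ValidationError("band_label must be non-empty")
        if self.size_bp is not None and self.size_bp <= 0:
            raise ValidationError(
                f"size_bp must be > 0, got {self.size_bp} for band "
                f"{self.primer_combination}:{self.band_label}"
            )

    @property
    def band_id(self) -> str:
        return f"{self.primer_combination}:{self.band_label}"


@dataclass
class MarkerMatrix:
    """Validated binary strains x bands matrix with primer-grouped bands.

    Parameters
    ----------
    strain_ids
        Ordered unique strain labels, at least two.
    bands
        Ordered band definitions; ``(primer_combination, band_label)`` unique.
    values
        ``(n_strains, n_bands)`` array of 0/1 entries.
    """

    strain_ids: list[str]
    bands: list[BandDef]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.strain_ids = list(self.strain_ids)
        self.bands = list(self.bands)
        self.values = np.asarray(self.values)
        if len(self.strain_ids) < 2:
            raise ValidationError(
                f"need >= 2 strains, got {len(self.strain_ids)}"
            )
        if len(set(self.strain_ids)) != len(self.strain_ids):
            dupes = sorted(
                s for s in set(self.strain_ids) if self.strain_ids.count(s) > 1
            )
            raise ValidationError(f"duplicate strain ids: {dupes}")
        ids = [b.band_id for b in self.bands]
        if len(set(ids)) != len(ids):
            dupes = sorted(i for i in set(ids) if ids.count(i) > 1)
            raise ValidationError(f"duplicate band ids: {dupes}")
        if not self.bands:
            raise ValidationError("matrix must contain at least one band")
        if self.values.shape != (len(self.strain_ids), len(self.bands)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.strain_ids)} strains x {len(self.bands)} bands"
            )
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"non-binary cell {self.values[i, j]!r} at strain "
                f"{self.strain_ids[i]!r}, band {self.bands[j].band_id!r}"
            )
        self.values = self.values.astype(np.int8)

    # -- accessors ---------------------------------------------------------

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def primer_combinations(self) -> list[str]:
        """Primer combinations in order of first appearance."""
        seen: dict[str, None] = {}
        for b in self.bands:
            seen.setdefault(b.primer_combination, None)
        return list(seen)

    def band_columns(self, primer_combination: str) -> list[int]:
        """Column indices of the bands of one primer combination."""
        cols = [
            j
            for j, b in enumerate(self.bands)
            if b.primer_combination == primer_combination
        ]
        if not cols:
            raise ValidationError(
                f"unknown primer combination {primer_combination!r}"
            )
        return cols

    def band_index(self, band_id: str) -> int:
        for j, b in enumerate(self.bands):
            if b.band_id == band_id:
                return j
        raise ValidationError(f"unknown band {band_id!r}")

    def strain_profile(self, strain_id: str) -> np.ndarray:
        try:
            i = self.strain_ids.index(strain_id)
        except ValueError:
            raise ValidationError(f"unknown strain {strain_id!r}") from None
        return self.values[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerMatrix):
            return NotImplemented
        return (
            self.strain_ids == other.strain_ids
            and self.bands == other.bands
            and np.array_equal(self.values, other.values)
        )


def _band_from_token(token: str) -> BandDef:
    parts = token.split(":")
    if len(parts) == 2:
        return BandDef(parts[0], parts[1])
    if len(parts) == 3:
        try:
            size = int(parts[2])
        except ValueError:
            raise ValidationError(
                f"band header token {token!r}: size must be an integer"
            ) from None
        return BandDef(parts[0], parts[1], size)
    raise ValidationError(
        f"band header token {token!r} is not "
        "'<primer>:<band>' or '<primer>:<band>:<size_bp>'"
    )


def _band_to_token(band: BandDef) -> str:
    if band.size_bp is None:
        return band.band_id
    return f"{band.band_id}:{band.size_bp}"


def read_matrix(path: str | Path) -> MarkerMatrix:
    """Read a band-matrix CSV and return a validated :class:`MarkerMatrix`.

    Band order and strain order are preserved from the file. Any non-binary
    cell, duplicate identifier, or single-strain file raises
    :class:`~trapdiv.errors.ValidationError` naming the offending entry.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file") from None
        if not header or header[0] != "strain":
            raise ValidationError(
                f"{path}: first header column must be 'strain', got "
                f"{header[0]!r}" if header else f"{path}: empty header"
            )
        bands = [_band_from_token(tok) for tok in header[1:]]
        strain_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(bands) + 1:
                raise ValidationError(
                    f"{path}:{lineno}: expected {len(bands) + 1} columns, "
                    f"got {len(row)}"
                )
            strain_ids.append(row[0])
            parsed: list[int] = []
            for tok, band in zip(row[1:], bands):
                if tok not in ("0", "1"):
                    raise ValidationError(
                        f"{path}:{lineno}: non-binary cell {tok!r} for strain "
                        f"{row[0]!r}, band {band.band_id!r}"
                    )
                parsed.append(int(tok))
            rows.append(parsed)
    if len(strain_ids) < 2:
        raise ValidationError(
            f"{path}: need >= 2 strains, got {len(strain_ids)}"
        )
    return MarkerMatrix(strain_ids, bands, np.array(rows, dtype=np.int8))


def write_matrix(m: MarkerMatrix, path: str | Path) -> None:
    """Write a MarkerMatrix in the CSV dialect read by :func:`read_matrix`.

    Output is byte-stable for a given matrix, and
    ``read_matrix(write_matrix(m)) == m``.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["strain"] + [_band_to_token(b) for b in m.bands])
    for i, sid in enumerate(m.strain_ids):
        writer.writerow([sid] + [str(int(v)) for v in m.values[i]])
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# Packaged reference panel (28 primer combinations of a 20-strain TRAP study)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Table1Row:
    """One printed row of the reference TRAP panel summary."""

    primer_name: str
    total_bands: int
    polymorphic_bands: int
    pct_polymorphism: float
    pic: float
    mi: float
    size_range_text: str

    @property
    def size_range(self) -> tuple[int, int]:
        lo, hi = self.size_range_text.split("-")
        return int(lo), int(hi)


@dataclass
class Table1Fixture:
    """The packaged 28-row per-primer summary of the reference TRAP panel."""

    rows: list[Table1Row] = field(default_factory=list)

    def __post_init__(self) -> None:
        for r in self.rows:
            if not (r.total_bands >= r.polymorphic_bands >= 0):
                raise ValidationError(
                    f"row {r.primer_name}: total_bands >= polymorphic_bands "
                    ">= 0 violated"
                )

    def row(self, primer_name: str) -> Table1Row:
        for r in self.rows:
            if r.primer_name == primer_name:
                return r
        raise KeyError(primer_name)

    def __len__(self) -> int:
        return len(self.rows)


def load_table1_fixture() -> Table1Fixture:
    """Load the packaged reference-panel summary (28 primer combinations)."""
    text = (
        resources.files("trapdiv.data")
        .joinpath("table1_trap_panel.csv")
        .read_text(encoding="utf-8")
    )
    rows = []
    for rec in csv.DictReader(io.StringIO(text)):
        rows.append(
            Table1Row(
                primer_name=rec["primer_combination"],
                total_bands=int(rec["total_bands"]),
                polymorphic_bands=int(rec["polymorphic_bands"]),
                pct_polymorphism=float(rec["pct_polymorphism"]),
                pic=float(rec["pic"]),
                mi=float(rec["mi"]),
                size_range_text=rec["size_range"],
            )
        )
    return Table1Fixture(rows)
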