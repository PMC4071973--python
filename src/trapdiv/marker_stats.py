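"""Per-primer polymorphism statistics for dominant markers.

For a dominant (presence/absence) band with presence frequency ``p`` the
polymorphism information content is the two-state gene-diversity form

    PIC = 1 - p^2 - (1 - p)^2 = 2 p (1 - p),

which is bounded by 0.5 (attained at p = 0.5). A primer combination's PIC is
the arithmetic mean of band PIC over its *polymorphic* bands, and its marker
index (MI) combines that mean with the band counts. Two MI conventions are in
circulation and both are exposed here:

``table``   MI = mean PIC x eta           (eta = total bands)
``formula`` MI = mean PIC x eta x beta    (beta = polymorphic fraction)

The ``table`` convention is the default because it is the one the reference
panel's printed values actually follow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from trapdiv.errors import ValidationError
from trapdiv.matrix_io import MarkerMatrix, Table1Fixture

logger = logging.getLogger(__name__)

MI_MODES = ("table", "formula")


@dataclass(frozen=True)
class PrimerStats:
    """Summary statistics of one primer combination (one panel-table row)."""

    primer_name: str
    n_total: int
    n_poly: int
    pct_poly: float
    pic_mean: float
    mi: float
    size_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_poly <= self.n_total:
            raise ValidationError(
                f"{self.primer_name}: 0 <= n_poly <= n_total violated"
            )
        if not 0.0 <= self.pic_mean <= 0.5 + 1e-12:
            raise ValidationError(
                f"{self.primer_name}: pic_mean {self.pic_mean} outside [0, 0.5]"
            )


@dataclass(frozen=True)
class PanelSummary:
    """All per-primer rows plus unweighted column means, sums and ranges."""

    rows: tuple[PrimerStats, ...]
    total_bands: int
    total_poly: int
    mean_total: float
    mean_poly: float
    mean_pct_poly: float
    mean_pic: float
    mean_mi: float
    min_total: int
    max_total: int
    min_poly: int
    max_poly: int
    min_pct_poly: float
    max_pct_poly: float
    min_pic: float
    max_pic: float
    min_mi: float
    max_mi: float

    def row(self, primer_name: str) -> PrimerStats:
        for r in self.rows:
            if r.primer_name == primer_name:
                return r
        raise KeyError(primer_name)

    def to_dataframe(self) -> pd.DataFrame:
        """Per-primer rows as a DataFrame, values at full precision."""
        return pd.DataFrame(
            {
                "primer_combination": [r.primer_name for r in self.rows],
                "total_bands": [r.n_total for r in self.rows],
                "polymorphic_bands": [r.n_poly for r in self.rows],
                "pct_polymorphism": [r.pct_poly for r in self.rows],
                "pic": [r.pic_mean for r in self.rows],
                "mi": [r.mi for r in self.rows],
                "size_range": [
                    "" if r.size_range is None
                    else f"{r.size_range[0]}-{r.size_range[1]}"
                    for r in self.rows
                ],
            }
        )

    def write_csv(self, path) -> None:
        """Panel table with totals / mean / min / max footer rows, 2-dp reals."""
        df = self.to_dataframe()
        for col in ("pct_polymorphism", "pic", "mi"):
            df[col] = df[col].map(lambda v: f"{v:.2f}")
        footer = pd.DataFrame(
            {
                "primer_combination": ["Total", "Minimum", "Maximum", "Mean"],
                "total_bands": [
                    self.total_bands, self.min_total, self.max_total,
                    f"{self.mean_total:.2f}",
                ],
                "polymorphic_bands": [
                    self.total_poly, self.min_poly, self.max_poly,
                    f"{self.mean_poly:.2f}",
                ],
                "pct_polymorphism": [
                    "", f"{self.min_pct_poly:.2f}", f"{self.max_pct_poly:.2f}",
                    f"{self.mean_pct_poly:.2f}",
                ],
                "pic": [
                    "", f"{self.min_pic:.2f}", f"{self.max_pic:.2f}",
                    f"{self.mean_pic:.2f}",
                ],
                "mi": [
                    "", f"{self.min_mi:.2f}", f"{self.max_mi:.2f}",
                    f"{self.mean_mi:.2f}",
                ],
                "size_range": ["", "", "", ""],
            }
        )
        pd.concat([df, footer], ignore_index=True).to_csv(path, index=False)


def band_frequency(m: MarkerMatrix, band_id: str) -> float:
    """Presence frequency of one band: strains scored 1 over all strains."""
    j = m.band_index(band_id)
    return float(m.values[:, j].sum()) / m.n_strains


def band_pic(p: float) -> float:
    """Two-state PIC of a dominant band with presence frequency ``p``.

    ``1 - p^2 - (1-p)^2 = 2p(1-p)``; symmetric in p and 1-p, maximal (0.5)
    at p = 0.5 and zero for monomorphic bands.
    """
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"presence frequency {p} outside [0, 1]")
    return 2.0 * p * (1.0 - p)


def is_polymorphic(m: MarkerMatrix, band_id: str) -> bool:
    """True iff both presence and absence are observed for the band."""
    return 0.0 < band_frequency(m, band_id) < 1.0


def primer_pic(m: MarkerMatrix, primer_combination: str) -> float:
    """Mean band PIC over the polymorphic bands of one primer combination.

    Returns 0.0 (with a logged warning) when no band is polymorphic.
    """
    cols = m.band_columns(primer_combination)
    pics = []
    for j in cols:
        p = float(m.values[:, j].sum()) / m.n_strains
        if 0.0 < p < 1.0:
            pics.append(band_pic(p))
    if not pics:
        logger.warning(
            "primer combination %s has no polymorphic band; PIC set to 0",
            primer_combination,
        )
        return 0.0
    return float(np.mean(pics))


def marker_index(
    pic_mean: float,
    n_total: int,
    pct_poly: float | None = None,
    mode: str = "table",
) -> float:
    """Marker index of a primer combination.

    ``mode='table'`` computes mean PIC x eta (eta = total band count), the
    convention the reference panel's printed column follows; ``mode='formula'``
    computes mean PIC x eta x beta with beta the polymorphic proportion
    (``pct_poly / 100``), and then requires ``pct_poly``.
    """
    if mode not in MI_MODES:
        raise ValidationError(f"mode must be one of {MI_MODES}, got {mode!r}")
    if pic_mean < 0 or n_total < 0 or (pct_poly is not None and pct_poly < 0):
        raise ValidationError("marker_index inputs must be non-negative")
    if mode == "table":
        return pic_mean * n_total
    if pct_poly is None:
        raise ValidationError("mode 'formula' requires pct_poly")
    return pic_mean * n_total * (pct_poly / 100.0)


def primer_stats(
    m: MarkerMatrix, primer_combination: str, mi_mode: str = "table"
) -> PrimerStats:
    """Full statistics row for one primer combination."""
    cols = m.band_columns(primer_combination)
    n_total = len(cols)
    n_poly = sum(
        1
        for j in cols
        if 0 < int(m.values[:, j].sum()) < m.n_strains
    )
    pct_poly = 100.0 * n_poly / n_total
    pic_mean = primer_pic(m, primer_combination)
    mi = marker_index(pic_mean, n_total, pct_poly, mode=mi_mode)
    sizes = [m.bands[j].size_bp for j in cols if m.bands[j].size_bp is not None]
    size_range = (min(sizes), max(sizes)) if sizes else None
    return PrimerStats(
        primer_name=primer_combination,
        n_total=n_total,
        n_poly=n_poly,
        pct_poly=pct_poly,
        pic_mean=pic_mean,
        mi=mi,
        size_range=size_range,
    )


def _summarize_rows(rows: list[PrimerStats]) -> PanelSummary:
    tot = [r.n_total for r in rows]
    pol = [r.n_poly for r in rows]
    pct = [r.pct_poly for r in rows]
    pic = [r.pic_mean for r in rows]
    mi = [r.mi for r in rows]
    return PanelSummary(
        rows=tuple(rows),
        total_bands=int(sum(tot)),
        total_poly=int(sum(pol)),
        mean_total=float(np.mean(tot)),
        mean_poly=float(np.mean(pol)),
        mean_pct_poly=float(np.mean(pct)),
        mean_pic=float(np.mean(pic)),
        mean_mi=float(np.mean(mi)),
        min_total=int(min(tot)),
        max_total=int(max(tot)),
        min_poly=int(min(pol)),
        max_poly=int(max(pol)),
        min_pct_poly=float(min(pct)),
        max_pct_poly=float(max(pct)),
        min_pic=float(min(pic)),
        max_pic=float(max(pic)),
        min_mi=float(min(mi)),
        max_mi=float(max(mi)),
    )


def summarize_panel(m: MarkerMatrix, mi_mode: str = "table") -> PanelSummary:
    """One :class:`PrimerStats` row per primer combination plus column
    totals, unweighted means, and min/max — the panel-level table."""
    rows = [primer_stats(m, pc, mi_mode=mi_mode) for pc in m.primer_combinations]
    return _summarize_rows(rows)


def summarize_fixture(fixture: Table1Fixture) -> PanelSummary:
    """Panel summary computed directly from printed per-primer rows.

    Used when only the published per-primer table is available (no raw band
    matrix): the printed values feed the same means/totals/ranges path as
    :func:`summarize_panel`.
    """
    rows = [
        PrimerStats(
            primer_name=r.primer_name,
            n_total=r.total_bands,
            n_poly=r.polymorphic_bands,
            pct_poly=r.pct_polymorphism,
            pic_mean=r.pic,
            mi=r.mi,
            size_range=r.size_range,
        )
        for r in fixture.rows
    ]
    return _summarize_rows(rows)
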