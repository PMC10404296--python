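"""UNSEEA ecosystem carbon accounting tables.

Land cover is reclassified into the six UNSEEA level-2 vegetated classes
(broadleaved, coniferous, mixed, mangroves, other woody vegetation, forest
plantations — the plantation layer overrides natural-forest labels).  Per
class the module aggregates the opening stock, the signed net flux and the
closing stock (closing = opening + net flux) in Tg C, splits the net flux
into net emissions (negative pixels) and net sequestration (positive
pixels), and attributes emissions to forest conversion (forest in 2010,
non-forest in 2018) versus forest degradation (forest at both epochs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import NODATA_INT, RasterGrid
from .synthetic import FOREST_LABELS, UNSEEA_CLASSES
from .uncertainty import ClassVariance

logger = logging.getLogger(__name__)


@dataclass
class UNSEEAClassMap:
    """Categorical raster of UNSEEA class codes plus the label list."""

    classes: RasterGrid
    labels: tuple[str, ...]
    source_resolution_m: float = 100.0
    resampling_note: str = "native"

    def label_of(self, code: int) -> str:
        return self.labels[code]

    def mask_of(self, label: str) -> np.ndarray:
        code = self.labels.index(label)
        return self.classes.data == code

    def present_labels(self) -> list[str]:
        valid = self.classes.valid_mask()
        codes = np.unique(self.classes.data[valid]).astype(int)
        return [self.labels[c] for c in codes]


def _nearest_upsample(data: np.ndarray, factor: int) -> np.ndarray:
    return np.kron(data, np.ones((factor, factor), dtype=data.dtype))


def reclassify_landcover(
    landcover: RasterGrid,
    plantation_mask: RasterGrid,
    mapping: dict[int, str],
    target_cell_m: float = 100.0,
) -> UNSEEAClassMap:
    """Map source land-cover codes to UNSEEA classes with plantation overlay.

    Coarser source grids are brought to the target cell size by
    nearest-neighbour resampling (integer block replication).  Any source
    code not covered by ``mapping`` raises, listing the offending codes.
    Plantation pixels inside forest labels are relabelled "plantation".
    """
    data = landcover.data
    note = "native"
    cell = landcover.cell_size_m
    if cell != target_cell_m:
        factor = cell / target_cell_m
        if factor < 1 or abs(factor - round(factor)) > 1e-9:
            raise ValueError(
                f"source cell {cell} m not an integer multiple of target "
                f"{target_cell_m} m"
            )
        data = _nearest_upsample(data, int(round(factor)))
        note = f"nearest-neighbour {cell:g}m -> {target_cell_m:g}m"
    valid = data != landcover.nodata
    codes = np.unique(data[valid]).astype(int)
    unmapped = [int(c) for c in codes if int(c) not in mapping]
    if unmapped:
        raise ValueError(f"unmapped source land-cover codes: {unmapped}")
    bad = [lab for lab in mapping.values() if lab not in UNSEEA_CLASSES]
    if bad:
        raise ValueError(f"mapping targets outside the UNSEEA classes: {bad}")

    labels = tuple(UNSEEA_CLASSES)
    out = np.full(data.shape, NODATA_INT, dtype=np.uint8)
    for code in codes:
        out[data == code] = labels.index(mapping[int(code)])

    pm = plantation_mask.data
    if plantation_mask.cell_size_m != target_cell_m:
        factor = int(round(plantation_mask.cell_size_m / target_cell_m))
        pm = _nearest_upsample(pm, factor)
    if pm.shape != out.shape:
        raise ValueError("plantation mask not co-registered with land cover")
    forest_codes = [labels.index(lab) for lab in FOREST_LABELS if lab in labels]
    overlay = (pm == 1) & np.isin(out, forest_codes)
    out[overlay] = labels.index("plantation")

    grid = RasterGrid(
        out,
        cell_size_m=target_cell_m,
        origin=landcover.origin,
        nodata=NODATA_INT,
        name="unseea_classes",
    )
    return UNSEEAClassMap(
        classes=grid,
        labels=labels,
        source_resolution_m=cell,
        resampling_note=note,
    )


MG_PER_TG = 1e6


def class_totals(
    opening_stock: RasterGrid,
    flux: RasterGrid,
    classmap: UNSEEAClassMap,
    cell_area_ha: float = 1.0,
) -> pd.DataFrame:
    """Per-class area and opening / net-flux / closing totals in Tg C.

    Closing is computed per pixel as opening + signed flux and then summed;
    by linearity this equals the sum of the opening and flux totals.
    """
    cm = classmap.classes
    cm.require_aligned(opening_stock, "opening stock")
    cm.require_aligned(flux, "flux map")
    valid = cm.valid_mask() & opening_stock.valid_mask() & flux.valid_mask()
    rows = []
    for label in classmap.present_labels():
        sel = classmap.mask_of(label) & valid
        n = int(sel.sum())
        if n == 0:
            logger.info("class_totals: class %s has no valid pixels; omitted", label)
            continue
        opening = float(opening_stock.data[sel].sum()) * cell_area_ha / MG_PER_TG
        net = float(flux.data[sel].sum()) * cell_area_ha / MG_PER_TG
        closing = float(
            (opening_stock.data[sel] + flux.data[sel]).sum()
        ) * cell_area_ha / MG_PER_TG
        rows.append(
            {
                "unseea_class": label,
                "n_pixels": n,
                "area_km2": n * cell_area_ha / 100.0,
                "opening_TgC": opening,
                "net_flux_TgC": net,
                "closing_TgC": closing,
            }
        )
    return pd.DataFrame(rows)


def emissions_split(
    flux: RasterGrid,
    classmap: UNSEEAClassMap,
    landcover_2010: RasterGrid,
    landcover_2018: RasterGrid,
    forest_labels_2010,
    forest_labels_2018=None,
    class_labels_2010=None,
    cell_area_ha: float = 1.0,
) -> pd.DataFrame:
    """Net emissions / sequestration per class with conversion attribution.

    Net emissions are the sum of negative-flux pixels, net sequestration of
    positive ones (zero-flux pixels contribute to neither).  Negative pixels
    are partitioned by the 2010/2018 forest transition: forest→forest is
    degradation, forest→non-forest conversion; negative pixels that were not
    forest in 2010 land in an "unattributed" residual column so the
    partition stays exhaustive.

    ``forest_labels_2010/2018`` are the class labels of the land-cover pair
    counted as forest; ``class_labels_2010`` maps 2010 codes to labels
    (defaults to indexing into the scenario class list).
    """
    forest_labels_2010 = set(forest_labels_2010)
    if not forest_labels_2010:
        raise ValueError("forest_labels must be non-empty")
    if forest_labels_2018 is None:
        forest_labels_2018 = forest_labels_2010
    cm = classmap.classes
    cm.require_aligned(flux, "flux map")
    cm.require_aligned(landcover_2010, "2010 land cover")
    cm.require_aligned(landcover_2018, "2018 land cover")

    def forest_mask(lc: RasterGrid, labels) -> np.ndarray:
        if class_labels_2010 is not None:
            codes = [
                i for i, lab in enumerate(class_labels_2010) if lab in labels
            ]
        else:
            codes = [i for i, lab in enumerate(UNSEEA_CLASSES) if lab in labels]
        return np.isin(lc.data, codes) & lc.valid_mask()

    f10 = forest_mask(landcover_2010, forest_labels_2010)
    f18 = forest_mask(landcover_2018, forest_labels_2018)

    valid = cm.valid_mask() & flux.valid_mask()
    neg = valid & (flux.data < 0)
    pos = valid & (flux.data > 0)
    rows = []
    for label in classmap.present_labels():
        sel = classmap.mask_of(label)
        scale = cell_area_ha / MG_PER_TG

        def tg(mask):
            return float(flux.data[sel & mask].sum()) * scale

        emissions = tg(neg)
        sequestration = tg(pos)
        degradation = tg(neg & f10 & f18)
        conversion = tg(neg & f10 & ~f18)
        unattributed = tg(neg & ~f10)
        rows.append(
            {
                "unseea_class": label,
                "net_emissions_TgC": emissions,
                "net_sequestration_TgC": sequestration,
                "emissions_degradation_TgC": degradation,
                "emissions_conversion_TgC": conversion,
                "emissions_unattributed_TgC": unattributed,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AccountTable:
    """Per-class UNSEEA carbon account with a totals row."""

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def summary(self) -> str:
        cols = [
            "unseea_class", "area_km2", "opening_TgC", "opening_sd_TgC",
            "net_flux_TgC", "net_flux_sd_TgC", "closing_TgC", "closing_sd_TgC",
        ]
        df = self.table[cols]
        lines = ["UNSEEA carbon account (Tg C; negative net flux = net emissions)"]
        header = (
            f"{'class':<16}{'area km2':>10}{'opening':>10}{'±':>8}"
            f"{'net flux':>10}{'±':>8}{'closing':>10}{'±':>8}"
        )
        lines.append(header)
        for row in df.itertuples(index=False):
            lines.append(
                f"{row.unseea_class:<16}{row.area_km2:>10.1f}"
                f"{row.opening_TgC:>10.2f}{row.opening_sd_TgC:>8.3f}"
                f"{row.net_flux_TgC:>10.2f}{row.net_flux_sd_TgC:>8.3f}"
                f"{row.closing_TgC:>10.2f}{row.closing_sd_TgC:>8.3f}"
            )
        return "\n".join(lines)


def build_account_table(
    totals: pd.DataFrame,
    variances: dict[str, dict[str, ClassVariance]] | None = None,
    splits: pd.DataFrame | None = None,
) -> AccountTable:
    """Assemble the accounting table: area, opening ± SD, net flux ± SD,
    closing ± SD per class, extended emission columns, and a totals row.

    ``variances`` maps class → {"opening": ClassVariance, "flux":
    ClassVariance}; closing SDs add the two variances (independent errors).
    Every class present in ``totals`` must be covered.  Closing is
    recomputed as opening + net flux so the accounting identity holds
    exactly.
    """
    df = totals.copy()
    df["closing_TgC"] = df["opening_TgC"] + df["net_flux_TgC"]

    if variances is not None:
        missing = [
            c for c in df["unseea_class"] if c not in variances
        ]
        if missing:
            raise ValueError(f"classes missing from variances: {missing}")
        open_sd, flux_sd, close_sd = [], [], []
        for c in df["unseea_class"]:
            vo, vf = variances[c]["opening"], variances[c]["flux"]
            open_sd.append(vo.sd_TgC)
            flux_sd.append(vf.sd_TgC)
            close_sd.append(float(np.sqrt(vo.variance_TgC2 + vf.variance_TgC2)))
        df["opening_sd_TgC"] = open_sd
        df["net_flux_sd_TgC"] = flux_sd
        df["closing_sd_TgC"] = close_sd
    else:
        df["opening_sd_TgC"] = np.nan
        df["net_flux_sd_TgC"] = np.nan
        df["closing_sd_TgC"] = np.nan

    if splits is not None:
        df = df.merge(splits, on="unseea_class", how="left")

    order = [
        "unseea_class", "n_pixels", "area_km2",
        "opening_TgC", "opening_sd_TgC",
        "net_flux_TgC", "net_flux_sd_TgC",
        "closing_TgC", "closing_sd_TgC",
    ]
    extra = [c for c in df.columns if c not in order]
    df = df[order + extra]

    total = {"unseea_class": "TOTAL"}
    for c in df.columns:
        if c == "unseea_class":
            continue
        if c.endswith("_sd_TgC"):
            # independent classes: total SD adds in quadrature
            total[c] = float(np.sqrt(np.nansum(df[c].to_numpy(float) ** 2)))
        else:
            total[c] = float(df[c].sum())
    df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    return AccountTable(table=df)
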