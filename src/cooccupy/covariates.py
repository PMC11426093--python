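"""Site covariates: transforms, standardization and collinearity screening.

Detection covariates are the four human-activity measures — distance to the
nearest paved road (DR, m), distance to the nearest settlement (DS, m), and
the relative abundance indices of human (RH) and cattle (RC).  RH and RC are
right-skewed with many zeros (cattle are absent from roughly half the sites),
so they pass through log(x+1) before standardization.  Occupancy covariates
are site latitude and longitude, standardized, included to absorb broad
spatial trends in occurrence.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteCovariates",
    "DesignMatrix",
    "prepare_covariates",
    "collinearity_screen",
    "read_covariates_csv",
]

DETECTION_COLUMNS = ("DR", "DS", "logRH", "logRC")
OCCUPANCY_COLUMNS = ("lat", "lon")


@dataclass(frozen=True)
class SiteCovariates:
    site_id: str
    DR: float  # distance to nearest paved road, m
    DS: float  # distance to nearest settlement, m
    RH: float  # RAI of human
    RC: float  # RAI of cattle
    lat: float
    lon: float

    def __post_init__(self):
        if self.DR <= 0 or self.DS <= 0:
            raise ValueError(f"site {self.site_id!r}: distances must be positive")
        if self.RH < 0 or self.RC < 0:
            raise ValueError(f"site {self.site_id!r}: RAI must be non-negative")


@dataclass
class DesignMatrix:
    """Standardized covariate matrices aligned to the detection histories.

    ``X_det`` holds the four detection covariates (DR, DS, logRH, logRC) and
    ``X_occ`` the two occupancy covariates (lat, lon), each centered and
    scaled to sample mean 0 / SD 1.  The transform parameters are stored so
    raw values can be recovered and new values mapped onto the fitted scale.
    """

    site_ids: list[str]
    X_det: np.ndarray  # (n, 4) standardized
    X_occ: np.ndarray  # (n, 2) standardized
    det_names: tuple[str, ...] = DETECTION_COLUMNS
    occ_names: tuple[str, ...] = OCCUPANCY_COLUMNS
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    log_offset: float = 1.0  # RH/RC go through log(x + offset)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.hstack([self.X_det, self.X_occ]),
            index=pd.Index(self.site_ids, name="site_id"),
            columns=list(self.det_names) + list(self.occ_names),
        )

    def standardize_raw(self, name: str, values) -> np.ndarray:
        """Map raw covariate values (e.g. RH in detections/100 days) onto the
        standardized scale used in the fit."""
        x = np.asarray(values, dtype=float)
        if name in ("RH", "RC"):
            name = "log" + name
            x = np.log(x + self.log_offset)
        return (x - self.means[name]) / self.sds[name]

    def destandardize(self, name: str, z) -> np.ndarray:
        """Inverse of standardization (returns raw DR/DS/RH/RC/lat/lon units)."""
        key = "log" + name if name in ("RH", "RC") else name
        x = np.asarray(z, dtype=float) * self.sds[key] + self.means[key]
        if name in ("RH", "RC"):
            x = np.exp(x) - self.log_offset
        return x

    def to_json(self, path) -> None:
        payload = {
            "site_ids": self.site_ids,
            "det_names": list(self.det_names),
            "occ_names": list(self.occ_names),
            "X_det": self.X_det.tolist(),
            "X_occ": self.X_occ.tolist(),
            "means": self.means,
            "sds": self.sds,
            "log_offset": self.log_offset,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DesignMatrix":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            site_ids=d["site_ids"],
            X_det=np.asarray(d["X_det"], dtype=float),
            X_occ=np.asarray(d["X_occ"], dtype=float),
            det_names=tuple(d["det_names"]),
            occ_names=tuple(d["occ_names"]),
            means=d["means"],
            sds=d["sds"],
            log_offset=d["log_offset"],
        )


def prepare_covariates(
    raw: Sequence[SiteCovariates] | pd.DataFrame, log_offset: float = 1.0
) -> DesignMatrix:
    """Transform and standardize site covariates.

    RH and RC are mapped through log(x + ``log_offset``) first (offset 1 keeps
    the transform defined at the many zero-RAI sites), then all six columns
    are centered and scaled.  Sites are ordered by site id to match the
    detection histories.
    """
    if isinstance(raw, pd.DataFrame):
        raw = [
            SiteCovariates(
                site_id=str(r.site_id), DR=float(r.DR), DS=float(r.DS),
                RH=float(r.RH), RC=float(r.RC), lat=float(r.lat), lon=float(r.lon),
            )
            for r in raw.itertuples(index=False)
        ]
    if len(raw) < 3:
        raise ValueError("need at least 3 sites to standardize covariates")
    raw = sorted(raw, key=lambda s: s.site_id)
    site_ids = [s.site_id for s in raw]

    cols = {
        "DR": np.array([s.DR for s in raw], dtype=float),
        "DS": np.array([s.DS for s in raw], dtype=float),
        "logRH": np.log(np.array([s.RH for s in raw], dtype=float) + log_offset),
        "logRC": np.log(np.array([s.RC for s in raw], dtype=float) + log_offset),
        "lat": np.array([s.lat for s in raw], dtype=float),
        "lon": np.array([s.lon for s in raw], dtype=float),
    }
    means, sds, std = {}, {}, {}
    for name, x in cols.items():
        mu = float(x.mean())
        sd = float(x.std(ddof=1))
        if sd == 0.0:
            raise ValueError(f"covariate {name!r} has zero variance")
        means[name], sds[name] = mu, sd
        std[name] = (x - mu) / sd

    return DesignMatrix(
        site_ids=site_ids,
        X_det=np.column_stack([std[c] for c in DETECTION_COLUMNS]),
        X_occ=np.column_stack([std[c] for c in OCCUPANCY_COLUMNS]),
        means=means,
        sds=sds,
        log_offset=log_offset,
    )


def collinearity_screen(dm: DesignMatrix, threshold: float = 0.6) -> pd.DataFrame:
    """All pairwise Pearson correlations among the prepared covariates.

    Pairs with |r| >= ``threshold`` are flagged (and raise a warning); a
    flagged pair is a modelling caution, not a hard failure — the screening
    convention in the source field is |r| < 0.6.
    """
    f = dm.frame()
    if len(f) < 3:
        raise ValueError("need at least 3 sites for a correlation screen")
    for c in f.columns:
        if float(f[c].std(ddof=1)) == 0.0:
            raise ValueError(f"covariate {c!r} has zero variance")
    names = list(f.columns)
    corr = f.corr(method="pearson")
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = float(corr.iloc[i, j])
            flagged = abs(r) >= threshold
            rows.append({"var1": names[i], "var2": names[j], "pearson_r": r, "flagged": flagged})
            if flagged:
                warnings.warn(
                    f"covariates {names[i]!r} and {names[j]!r} are correlated "
                    f"(|r| = {abs(r):.2f} >= {threshold})",
                    stacklevel=2,
                )
    return pd.DataFrame(rows)


def read_covariates_csv(path) -> list[SiteCovariates]:
    df = pd.read_csv(path, dtype={"site_id": str})
    return [
        SiteCovariates(
            site_id=str(r.site_id), DR=float(r.DR), DS=float(r.DS),
            RH=float(r.RH), RC=float(r.RC), lat=float(r.lat), lon=float(r.lon),
        )
        for r in df.itertuples(index=False)
    ]
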