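"""Normative map construction and abnormality scoring.

A normative map stores, for every atlas region and frequency band, the
mean and SD of relative log band power across a cohort of presumed
non-pathological recordings. A patient's regional values are z-scored
against the map; the region's *abnormality* in a window is the maximum
absolute z-score across the five bands.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import BAND_NAMES
from .bandpower import RegionalBandPower

__all__ = [
    "NormativeMap",
    "AbnormalityMatrix",
    "build_normative_map",
    "zscore",
    "abnormality",
    "normalize_abnormality_window",
    "score_patient",
]

logger = logging.getLogger(__name__)


@dataclass
class NormativeMap:
    """Per (region, band) mean/SD of relative log band power.

    ``mu`` and ``sigma`` are (n_regions, n_bands) arrays aligned with
    ``region_ids`` and ``band_names``; ``n_subjects`` counts cohort
    coverage per region. Provenance (cohort id) is carried for
    reproducibility of downstream analyses.
    """

    region_ids: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    n_subjects: np.ndarray
    band_names: tuple[str, ...] = BAND_NAMES
    cohort_id: str = "unspecified"
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.n_subjects = np.asarray(self.n_subjects, dtype=int)
        if np.any(self.sigma <= 0):
            raise ValueError("normative map sigma must be strictly positive")
        self._index = {r: i for i, r in enumerate(self.region_ids)}

    def __contains__(self, region_id: str) -> bool:
        return region_id in self._index

    def row(self, region_id: str) -> tuple[np.ndarray, np.ndarray]:
        i = self._index[region_id]
        return self.mu[i], self.sigma[i]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.region_ids):
            for j, b in enumerate(self.band_names):
                rows.append((r, b, self.mu[i, j], self.sigma[i, j], self.n_subjects[i]))
        return pd.DataFrame(rows, columns=["region_id", "band", "mu", "sigma", "n_subjects"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "cohort_id": self.cohort_id,
                    "band_names": list(self.band_names),
                    "regions": {
                        r: {
                            "mu": self.mu[i].tolist(),
                            "sigma": self.sigma[i].tolist(),
                            "n_subjects": int(self.n_subjects[i]),
                        }
                        for i, r in enumerate(self.region_ids)
                    },
                },
                indent=1,
            )
        )

    @classmethod
    def from_csv(cls, path: str | Path, cohort_id: str = "unspecified") -> "NormativeMap":
        df = pd.read_csv(path)
        regions = list(dict.fromkeys(df["region_id"].astype(str)))
        bands = tuple(dict.fromkeys(df["band"]))
        piv_mu = df.pivot(index="region_id", columns="band", values="mu").loc[regions, list(bands)]
        piv_sd = df.pivot(index="region_id", columns="band", values="sigma").loc[regions, list(bands)]
        n = df.groupby("region_id", sort=False)["n_subjects"].first().loc[regions]
        return cls(
            region_ids=regions,
            mu=piv_mu.to_numpy(),
            sigma=piv_sd.to_numpy(),
            n_subjects=n.to_numpy(),
            band_names=bands,
            cohort_id=cohort_id,
        )


@dataclass
class AbnormalityMatrix:
    """Max-|z| abnormality per (window, region); NaN where undefined."""

    values: np.ndarray  # (n_windows, n_regions), >= 0 or NaN
    region_ids: list[str]
    window_starts: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.window_starts = np.asarray(self.window_starts, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)

    def normalized(self) -> np.ndarray:
        """Window-normalised view: each valid window's abnormalities sum to 1.

        For display/heatmaps; rank order within a window is preserved, so
        D_RS is identical on raw and normalised values.
        """
        out = np.full_like(self.values, np.nan)
        for t in np.nonzero(self.valid)[0]:
            out[t] = normalize_abnormality_window(self.values[t])
        return out

    def to_frame(self, patient_id: str | None = None) -> pd.DataFrame:
        idx = np.nonzero(self.valid)[0]
        nr = len(self.region_ids)
        df = pd.DataFrame(
            {
                "window_start_s": np.repeat(self.window_starts[idx], nr),
                "region_id": np.tile(self.region_ids, idx.size),
                "abnormality": self.values[idx].ravel(),
            }
        )
        if patient_id is not None:
            df.insert(0, "patient_id", patient_id)
        return df


def build_normative_map(
    cohort: pd.DataFrame, min_subjects: int = 5, cohort_id: str = "unspecified"
) -> NormativeMap:
    """Estimate the normative map from per-subject region-level band powers.

    ``cohort`` is a long table with columns (subject_id, region_id,
    delta, theta, alpha, beta, gamma), one row per subject x covered
    region. Per region and band the mean and sample SD (n-1 denominator)
    are taken across covering subjects. Regions covered by fewer than
    ``min_subjects`` subjects, or with a degenerate (zero) SD in any
    band, are excluded.
    """
    if cohort.empty:
        raise ValueError("empty normative cohort")
    bands = [b for b in BAND_NAMES if b in cohort.columns]
    if len(bands) != len(BAND_NAMES):
        raise ValueError(f"cohort table must contain band columns {BAND_NAMES}")
    grouped = cohort.groupby("region_id", sort=True)
    region_ids, mus, sds, counts = [], [], [], []
    for region, sub in grouped:
        n = sub["subject_id"].nunique()
        if n < min_subjects:
            logger.info("region %s excluded: coverage %d < %d subjects", region, n, min_subjects)
            continue
        vals = sub[list(BAND_NAMES)].to_numpy(dtype=float)
        mu = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=1)
        if np.any(sd == 0):
            logger.info("region %s excluded: zero SD in at least one band", region)
            continue
        region_ids.append(str(region))
        mus.append(mu)
        sds.append(sd)
        counts.append(n)
    if not region_ids:
        raise ValueError("no region satisfied the coverage rule; normative map is empty")
    return NormativeMap(
        region_ids=region_ids,
        mu=np.array(mus),
        sigma=np.array(sds),
        n_subjects=np.array(counts),
        cohort_id=cohort_id,
    )


def zscore(b: np.ndarray, map_: NormativeMap, region_id: str) -> np.ndarray:
    """z_{f,i,t} = (b_{f,i,t} - mu_{f,i}) / sigma_{f,i} per band.

    Raises KeyError if the region is absent from the map (callers drop
    such regions from the analysis, mirroring lack-of-coverage handling).
    """
    if region_id not in map_:
        raise KeyError(f"region {region_id!r} not covered by the normative map")
    mu, sigma = map_.row(region_id)
    return (np.asarray(b, dtype=float) - mu) / sigma


def abnormality(z_vector: np.ndarray) -> float:
    """Band-power abnormality: maximum absolute z-score across bands."""
    z = np.asarray(z_vector, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z-scores must be finite")
    return float(np.max(np.abs(z)))


def normalize_abnormality_window(abnormalities: np.ndarray) -> np.ndarray:
    """Scale one window's regional abnormalities to sum to 1."""
    a = np.asarray(abnormalities, dtype=float)
    if a.size == 0:
        raise ValueError("empty window")
    total = np.nansum(a)
    if total <= 0:
        raise ValueError("cannot normalise an all-zero abnormality window")
    return a / total


def score_patient(bp: RegionalBandPower, map_: NormativeMap) -> AbnormalityMatrix:
    """Score a patient's band-power tensor against the normative map.

    Regions without map coverage are dropped with a logged notice.
    Vectorised: abnormality[t, i] = max_f |(b[t,i,f] - mu[i,f]) / sigma[i,f]|.
    """
    keep = [i for i, r in enumerate(bp.region_ids) if r in map_]
    dropped = [r for r in bp.region_ids if r not in map_]
    if dropped:
        logger.info("regions without normative coverage dropped: %s", ", ".join(dropped))
    if not keep:
        raise ValueError("no patient region is covered by the normative map")
    regions = [bp.region_ids[i] for i in keep]
    mu = np.stack([map_.row(r)[0] for r in regions])
    sigma = np.stack([map_.row(r)[1] for r in regions])
    z = (bp.values[:, keep, :] - mu[None, :, :]) / sigma[None, :, :]
    vals = np.max(np.abs(z), axis=2)
    return AbnormalityMatrix(
        values=vals, region_ids=regions, window_starts=bp.window_starts, valid=bp.valid.copy()
    )
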