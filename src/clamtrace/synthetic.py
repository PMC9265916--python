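"""Synthetic per-sample data with the site-level structure of the study.

The raw per-clam measurements behind the published site summaries are not
deposited, so downstream stages are exercised on synthetic samples drawn
from the printed site-level statistics:

- ``korea_table1`` — bulk δ13C/δ15N mean ± SD and n for the 17 Korean sites
  (102 clams across the CC, JB, JN and GN coastal provinces);
- ``csia_table4`` — δ13C of six individual fatty acids, mean ± SD per site,
  three clams per site (51 total);
- ``countries_table6`` — country-level bulk δ13C/δ15N for China (n = 15),
  DPR Korea (n = 16) and Korea (n = 102);
- ``fa_profiles_synthetic`` — constructed (NOT transcribed) 15-FA relative
  compositions per site.  The per-site FA abundances were never published;
  these profiles are synthetic stand-ins that respect the published
  compositional ranges (SFA 26.20–65.48%, PUFA 10.23–32.33% of total FA),
  the DHA/EPA > 1 signature of GN, and the named biomarker tendencies.

Gaussian features are drawn independently per feature (only marginal
mean ± SD are published, so no assay covariance can be honoured); FA
compositions are drawn from a Dirichlet centred on the site profile, which
guarantees nonnegativity and unit sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._round import exact_fraction, round_half_up
from .fatty_acids import FA_NAMES

__all__ = [
    "SiteSpec",
    "SampleRecord",
    "builtin_fixtures",
    "generate_samples",
    "merge_specs",
    "samples_to_frame",
    "frame_to_samples",
    "write_samples_csv",
    "read_samples_csv",
    "specs_to_yaml",
    "specs_from_yaml",
    "site_weighted_average",
]

# "KOR" is an aggregate pseudo-region used by the country-level fixture,
# where the 102 Korean clams are pooled across the four provinces.
REGIONS = ("CC", "JB", "JN", "GN", "CHN", "NK", "KOR")
COUNTRIES = ("KOR", "CHN", "NK")

#: Default Dirichlet concentration: alpha = dispersion × composition.  At
#: 500 the per-FA spread is a couple of percentage points for the major
#: FAs, the scale of real assay repeatability.
DEFAULT_FA_DISPERSION = 500.0


@dataclass
class SiteSpec:
    """Per-site generative parameters: feature mean/SD pairs and sample n."""

    site_id: str
    region: str
    country: str
    n: int
    gaussian_features: dict[str, tuple[float, float]] = field(default_factory=dict)
    fa_composition: dict[str, float] | None = None
    fa_dispersion: float | None = None

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.country not in COUNTRIES:
            raise ValueError(f"unknown country {self.country!r}")
        if self.n < 1:
            raise ValueError(f"site {self.site_id}: n must be >= 1, got {self.n}")
        for name, (mean, sd) in self.gaussian_features.items():
            if sd < 0:
                raise ValueError(f"site {self.site_id}: negative sd for {name}")
        if self.fa_composition is not None:
            vals = np.array(list(self.fa_composition.values()), dtype=float)
            if np.any(vals < 0):
                raise ValueError(f"site {self.site_id}: negative FA fraction")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"site {self.site_id}: FA composition sums to {vals.sum()!r}, not 1"
                )
            if self.fa_dispersion is None:
                self.fa_dispersion = DEFAULT_FA_DISPERSION
            if self.fa_dispersion <= 0:
                raise ValueError(f"site {self.site_id}: fa_dispersion must be > 0")


@dataclass
class SampleRecord:
    """One clam: identity labels plus a feature map."""

    sample_id: str
    site_id: str
    region: str
    country: str
    features: dict[str, float]


# --- printed site-level statistics (bulk isotopes, 17 Korean sites) --------
# (site_id, region, n, d13C mean, d13C sd, d15N mean, d15N sd)
_KOREA_TABLE1 = [
    ("CC-1", "CC", 5, -18.0, 0.2, 8.9, 0.2),
    ("CC-2", "CC", 5, -18.3, 0.3, 6.8, 0.3),
    ("CC-3", "CC", 5, -18.4, 0.1, 6.4, 0.4),
    ("CC-4", "CC", 5, -17.6, 0.4, 9.1, 0.2),
    ("CC-5", "CC", 5, -17.5, 0.3, 8.6, 0.4),
    ("JB-1", "JB", 10, -17.1, 0.1, 9.6, 0.4),
    ("JB-2", "JB", 5, -16.6, 0.3, 9.1, 0.3),
    ("JB-3", "JB", 5, -17.4, 0.1, 10.0, 0.3),
    ("JB-4", "JB", 5, -16.4, 0.4, 8.7, 0.4),
    ("JN-1", "JN", 10, -16.5, 0.3, 7.7, 0.1),
    ("JN-2", "JN", 3, -17.1, 0.1, 10.0, 0.2),
    ("JN-3", "JN", 3, -16.9, 0.2, 9.0, 0.1),
    ("JN-4", "JN", 10, -16.9, 0.2, 9.1, 0.1),
    ("GN-1", "GN", 8, -16.8, 0.3, 8.8, 0.2),
    ("GN-2", "GN", 10, -15.7, 0.1, 10.6, 0.2),
    ("GN-3", "GN", 3, -16.3, 0.1, 9.8, 0.2),
    ("GN-4", "GN", 5, -15.8, 0.2, 11.0, 0.1),
]

#: δ13C-FA feature-name prefix; full names look like "d13C_16:0".
CSIA_PREFIX = "d13C_"

# (site_id, then (mean, sd) for 16:0, 18:0, 18:1n-7, 18:1n-9, 20:1n-7, 20:1n-9)
_CSIA_TABLE4 = [
    ("CC-1", (-23.1, 0.4), (-24.6, 0.4), (-20.9, 0.8), (-15.2, 0.7), (-22.9, 0.5), (-21.0, 0.7)),
    ("CC-2", (-24.4, 0.4), (-25.3, 0.4), (-22.5, 0.4), (-15.6, 0.5), (-25.0, 0.3), (-22.4, 0.3)),
    ("CC-3", (-24.4, 0.4), (-25.3, 0.4), (-22.2, 0.3), (-15.5, 0.4), (-24.6, 0.3), (-21.3, 0.5)),
    ("CC-4", (-25.0, 0.5), (-25.3, 0.3), (-21.1, 0.7), (-18.5, 0.5), (-20.7, 0.5), (-19.9, 0.3)),
    ("CC-5", (-24.9, 0.4), (-25.0, 0.3), (-20.2, 0.4), (-17.9, 0.4), (-20.6, 0.6), (-20.4, 0.5)),
    ("JB-1", (-20.4, 0.5), (-24.5, 0.4), (-20.6, 0.5), (-15.6, 0.5), (-21.0, 0.4), (-20.9, 0.4)),
    ("JB-2", (-21.9, 0.4), (-21.4, 0.8), (-21.4, 0.5), (-15.0, 0.7), (-21.1, 0.9), (-21.6, 0.5)),
    ("JB-3", (-26.8, 0.4), (-26.1, 0.8), (-24.5, 0.7), (-19.6, 0.5), (-24.8, 0.6), (-21.7, 0.6)),
    ("JB-4", (-23.5, 0.4), (-21.2, 0.3), (-21.2, 0.4), (-17.5, 0.5), (-21.5, 0.4), (-23.6, 0.5)),
    ("JN-1", (-22.2, 0.4), (-19.8, 0.3), (-20.7, 0.5), (-16.8, 0.5), (-20.6, 0.5), (-21.3, 0.5)),
    ("JN-2", (-23.2, 0.3), (-19.8, 0.4), (-22.0, 0.5), (-18.0, 0.4), (-21.5, 0.5), (-23.1, 0.5)),
    ("JN-3", (-23.4, 0.4), (-21.2, 0.6), (-22.6, 0.5), (-18.0, 0.4), (-20.9, 0.6), (-23.3, 0.4)),
    ("JN-4", (-23.5, 0.3), (-20.6, 0.5), (-22.1, 0.6), (-18.0, 0.4), (-21.8, 0.4), (-23.4, 0.5)),
    ("GN-1", (-24.5, 0.6), (-24.2, 0.6), (-27.1, 0.7), (-19.5, 0.6), (-26.1, 0.5), (-23.6, 0.6)),
    ("GN-2", (-21.6, 0.5), (-22.1, 0.3), (-25.6, 0.6), (-17.8, 0.6), (-24.6, 0.5), (-18.0, 0.6)),
    ("GN-3", (-21.9, 0.3), (-22.2, 0.4), (-25.5, 0.6), (-17.8, 0.3), (-24.8, 0.3), (-18.0, 0.5)),
    ("GN-4", (-22.0, 0.5), (-22.2, 0.7), (-25.7, 0.5), (-17.8, 0.4), (-24.8, 0.5), (-18.1, 0.3)),
]

_CSIA_FA_ORDER = ("16:0", "18:0", "18:1n-7", "18:1n-9", "20:1n-7", "20:1n-9")

# (id/region/country, n, d13C mean, sd, d15N mean, sd)
_COUNTRIES_TABLE6 = [
    ("CHN", "CHN", "CHN", 15, -17.58, 0.39, 9.67, 0.72),
    ("NK", "NK", "NK", 16, -17.69, 0.38, 8.95, 0.24),
    ("KOR", "KOR", "KOR", 102, -16.94, 0.79, 9.01, 1.18),
]

# --- constructed regional 15-FA templates (synthetic; percent of total) ----
# CC diatom-leaning (16:1n-7, EPA high); JB bacterial markers (15:0, 17:0,
# 18:1n-7) elevated; JN SFA-rich; GN flagellate-dominated (18:1n-9, DHA,
# DHA/EPA > 1); CHN diatom-dominant; NK highest MUFA.
REGION_FA_TEMPLATES: dict[str, dict[str, float]] = {
    "CC": dict(zip(FA_NAMES, [3.5, 1.5, 26.0, 2.0, 13.0,
                              9.0, 4.5, 3.5, 2.5, 2.5,
                              2.0, 1.5, 3.5, 16.0, 9.0])),
    "JB": dict(zip(FA_NAMES, [3.0, 2.5, 28.0, 3.5, 14.0,
                              6.0, 7.0, 3.0, 2.0, 2.0,
                              2.5, 1.5, 3.0, 12.0, 10.0])),
    "JN": dict(zip(FA_NAMES, [4.0, 2.0, 31.0, 2.5, 16.0,
                              5.5, 5.0, 4.0, 2.5, 2.5,
                              2.0, 1.5, 3.5, 10.0, 8.0])),
    "GN": dict(zip(FA_NAMES, [3.0, 1.5, 27.0, 1.5, 13.5,
                              4.5, 3.5, 8.0, 3.0, 3.0,
                              2.0, 1.5, 3.0, 10.0, 15.0])),
    "CHN": dict(zip(FA_NAMES, [3.5, 2.8, 29.0, 2.0, 15.0,
                               9.5, 6.5, 2.5, 1.8, 1.7,
                               3.5, 1.2, 2.5, 13.0, 5.5])),
    "NK": dict(zip(FA_NAMES, [3.0, 1.8, 26.0, 1.7, 12.5,
                              7.0, 7.5, 5.0, 4.5, 5.0,
                              2.0, 1.5, 3.0, 11.5, 8.0])),
}


def _site_fa_composition(region: str, site_index: int) -> dict[str, float]:
    """Deterministic per-site variant of the regional template.

    Site j trades a little 16:0 against 18:0 and EPA against DHA so sites
    within a region are distinguishable but stay near the regional profile.
    """
    profile = dict(REGION_FA_TEMPLATES[region])
    shift = 0.6 * (site_index - 1.5)
    profile["16:0"] += shift
    profile["18:0"] -= 0.5 * shift
    profile["20:5n-3"] += 0.3 * shift
    profile["22:6n-3"] -= 0.3 * shift
    total = sum(profile.values())
    return {name: value / total for name, value in profile.items()}


def _korea_table1_specs() -> list[SiteSpec]:
    return [
        SiteSpec(
            site_id=site,
            region=region,
            country="KOR",
            n=n,
            gaussian_features={"d13C": (c_mean, c_sd), "d15N": (n_mean, n_sd)},
        )
        for site, region, n, c_mean, c_sd, n_mean, n_sd in _KOREA_TABLE1
    ]


def _csia_table4_specs() -> list[SiteSpec]:
    specs = []
    for row in _CSIA_TABLE4:
        site = row[0]
        region = site.split("-")[0]
        features = {
            f"{CSIA_PREFIX}{fa}": pair for fa, pair in zip(_CSIA_FA_ORDER, row[1:])
        }
        specs.append(
            SiteSpec(site_id=site, region=region, country="KOR", n=3,
                     gaussian_features=features)
        )
    return specs


def _countries_table6_specs() -> list[SiteSpec]:
    return [
        SiteSpec(
            site_id=site,
            region=region,
            country=country,
            n=n,
            gaussian_features={"d13C": (c_mean, c_sd), "d15N": (n_mean, n_sd)},
        )
        for site, region, country, n, c_mean, c_sd, n_mean, n_sd in _COUNTRIES_TABLE6
    ]


def _fa_profiles_specs() -> list[SiteSpec]:
    specs = []
    for row in _KOREA_TABLE1:
        site, region = row[0], row[1]
        site_index = int(site.split("-")[1]) - 1
        specs.append(
            SiteSpec(
                site_id=site,
                region=region,
                country="KOR",
                n=3,
                fa_composition=_site_fa_composition(region, site_index),
            )
        )
    return specs


_FIXTURES = {
    "korea_table1": _korea_table1_specs,
    "csia_table4": _csia_table4_specs,
    "countries_table6": _countries_table6_specs,
    "fa_profiles_synthetic": _fa_profiles_specs,
}


def builtin_fixtures(name: str) -> list[SiteSpec]:
    """Return the registered site specs for one built-in fixture set.

    ``"korea_table1"``, ``"csia_table4"`` and ``"countries_table6"`` carry
    the published site-level mean ± SD and n verbatim;
    ``"fa_profiles_synthetic"`` carries constructed compositions (see module
    docstring).
    """
    try:
        factory = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    return factory()


def merge_specs(base: list[SiteSpec], *others: list[SiteSpec]) -> list[SiteSpec]:
    """Merge feature blocks of several fixture sets site-by-site.

    Sample counts come from ``base``; Gaussian features are unioned and FA
    compositions taken from the first set that defines them.  Sites missing
    from an ``others`` set simply contribute nothing for that block.
    """
    merged = []
    for spec in base:
        gaussian = dict(spec.gaussian_features)
        fa_comp = dict(spec.fa_composition) if spec.fa_composition else None
        fa_disp = spec.fa_dispersion
        for other in others:
            match = next((s for s in other if s.site_id == spec.site_id), None)
            if match is None:
                continue
            gaussian.update(match.gaussian_features)
            if fa_comp is None and match.fa_composition is not None:
                fa_comp = dict(match.fa_composition)
                fa_disp = match.fa_dispersion
        merged.append(
            SiteSpec(
                site_id=spec.site_id,
                region=spec.region,
                country=spec.country,
                n=spec.n,
                gaussian_features=gaussian,
                fa_composition=fa_comp,
                fa_dispersion=fa_disp,
            )
        )
    return merged


def generate_samples(specs: list[SiteSpec], seed: int = 0) -> list[SampleRecord]:
    """Draw Σ n per-sample records from the site specs, reproducibly.

    Gaussian features are independent normals per (mean, sd); an sd of 0
    yields the mean exactly.  FA compositions are Dirichlet draws with
    alpha = fa_dispersion × composition, rescaled to percent (sum 100).
    The same seed always yields the same records.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    rng = np.random.default_rng(seed)
    records: list[SampleRecord] = []
    for spec in specs:
        for k in range(spec.n):
            features: dict[str, float] = {}
            for name, (mean, sd) in spec.gaussian_features.items():
                features[name] = mean if sd == 0 else float(rng.normal(mean, sd))
            if spec.fa_composition is not None:
                names = list(spec.fa_composition)
                alpha = spec.fa_dispersion * np.array(
                    [spec.fa_composition[n_] for n_ in names]
                )
                draw = rng.dirichlet(alpha)
                draw = 100.0 * draw / draw.sum()
                features.update(dict(zip(names, draw)))
            records.append(
                SampleRecord(
                    sample_id=f"{spec.site_id}-{k + 1:03d}",
                    site_id=spec.site_id,
                    region=spec.region,
                    country=spec.country,
                    features=features,
                )
            )
    return records


_ID_COLUMNS = ["sample_id", "site_id", "region", "country"]


def samples_to_frame(records: list[SampleRecord]) -> pd.DataFrame:
    """Wide table: identity columns then feature columns (stable order)."""
    feature_order: list[str] = []
    for rec in records:
        for name in rec.features:
            if name not in feature_order:
                feature_order.append(name)
    rows = [
        {
            "sample_id": r.sample_id,
            "site_id": r.site_id,
            "region": r.region,
            "country": r.country,
            **r.features,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_ID_COLUMNS + feature_order)


def frame_to_samples(frame: pd.DataFrame) -> list[SampleRecord]:
    feature_cols = [c for c in frame.columns if c not in _ID_COLUMNS]
    return [
        SampleRecord(
            sample_id=str(row["sample_id"]),
            site_id=str(row["site_id"]),
            region=str(row["region"]),
            country=str(row["country"]),
            features={c: float(row[c]) for c in feature_cols if pd.notna(row[c])},
        )
        for _, row in frame.iterrows()
    ]


def write_samples_csv(records: list[SampleRecord] | pd.DataFrame, path) -> None:
    frame = records if isinstance(records, pd.DataFrame) else samples_to_frame(records)
    frame.to_csv(path, index=False, encoding="utf-8")


def read_samples_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def specs_to_yaml(specs: list[SiteSpec], path=None) -> str:
    """Serialize site specs to YAML (keys mirror SiteSpec fields)."""
    payload = []
    for s in specs:
        entry = {
            "site_id": s.site_id,
            "region": s.region,
            "country": s.country,
            "n": s.n,
            "gaussian_features": {k: [float(m), float(sd)] for k, (m, sd) in s.gaussian_features.items()},
        }
        if s.fa_composition is not None:
            entry["fa_composition"] = {k: float(v) for k, v in s.fa_composition.items()}
            entry["fa_dispersion"] = float(s.fa_dispersion)
        payload.append(entry)
    text = yaml.safe_dump(payload, sort_keys=False, allow_unicode=True)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def specs_from_yaml(source) -> list[SiteSpec]:
    """Load site specs from a YAML string or file path."""
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source
    payload = yaml.safe_load(text)
    specs = []
    for entry in payload:
        specs.append(
            SiteSpec(
                site_id=entry["site_id"],
                region=entry["region"],
                country=entry["country"],
                n=int(entry["n"]),
                gaussian_features={
                    k: (float(v[0]), float(v[1]))
                    for k, v in entry.get("gaussian_features", {}).items()
                },
                fa_composition=entry.get("fa_composition"),
                fa_dispersion=entry.get("fa_dispersion"),
            )
        )
    return specs


def site_weighted_average(specs: list[SiteSpec], feature: str, ndigits: int = 1) -> float:
    """Sample-size-weighted mean of a feature's site means, half-up rounded.

    Computed in exact rational arithmetic from the printed decimals so that
    half-way cases round deterministically.
    """
    total = sum(s.n for s in specs)
    if total == 0:
        raise ValueError("no samples in specs")
    acc = sum(exact_fraction(s.gaussian_features[feature][0]) * s.n for s in specs)
    return round_half_up(acc / total, ndigits)
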