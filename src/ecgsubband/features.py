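"""54-dimensional per-record feature vectors and the ANOVA feature screen.

Each record is normalized, decomposed into six wavelet sub-bands, and for
every band three Hjorth descriptors and six entropies are computed:
6 bands x 9 features = 54 values. Ordering is band-major and frozen
([cA5 block, cD5, ..., cD1]; within a block Hjorth first, then entropies)
so that feature CSVs are reproducible byte for byte.

The ANOVA screen runs a one-way fixed-effects ANOVA per feature column
across the rhythm classes and reports F, the raw p-value (optionally a
Bonferroni-adjusted column), and per-class mean +/- SD.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import entropy as ent
from . import hjorth as hj
from .errors import FeatureExtractionError, UndefinedEntropyError
from .signal_io import ECGSignal, normalize
from .wavelet import (
    DEFAULT_LEVELS,
    DEFAULT_MODE,
    DEFAULT_WAVELET,
    band_names,
    band_signal,
    dwt_decompose,
)

logger = logging.getLogger("ecgsubband")

HJORTH_FEATURES = ("activity", "mobility", "complexity")
FEATURE_KINDS = HJORTH_FEATURES + ent.ENTROPY_NAMES  # 9 per band
BANDS = tuple(band_names(DEFAULT_LEVELS))  # cA5, cD5, ..., cD1

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{band}_{feat}" for band in BANDS for feat in FEATURE_KINDS
)  # 54 names, band-major


@dataclass(frozen=True)
class ExtractionConfig:
    """Resolved settings used for one extraction run (stored in metadata)."""

    wavelet_name: str = DEFAULT_WAVELET
    levels: int = DEFAULT_LEVELS
    mode: str = DEFAULT_MODE
    entropy: ent.EntropyParams = field(default_factory=ent.EntropyParams)

    def to_dict(self) -> dict:
        return {
            "wavelet_name": self.wavelet_name,
            "levels": self.levels,
            "mode": self.mode,
            "entropy": self.entropy.to_dict(),
        }


@dataclass
class FeatureVector:
    """One record's ordered 54-value feature vector."""

    values: np.ndarray
    names: tuple[str, ...]
    label: str | None
    record_id: str | None
    meta: dict

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.names):
            raise ValueError("values/names length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")


def extract_features(x: ECGSignal, config: ExtractionConfig | None = None) -> FeatureVector:
    """normalize -> 5-level DWT -> 3 Hjorth + 6 entropy features per band.

    Features are computed on each band's band-limited reconstruction
    (every other band zeroed before the inverse transform), which keeps
    full temporal resolution in the deepest bands. Degenerate-signal and
    undefined-entropy conditions are re-raised as
    ``FeatureExtractionError`` carrying the band and feature name.
    """
    cfg = config or ExtractionConfig()
    z = normalize(x)
    dec = dwt_decompose(z, levels=cfg.levels, wavelet_name=cfg.wavelet_name, mode=cfg.mode)
    values: list[float] = []
    for bi, band_name in enumerate(dec.band_names):
        coeffs = band_signal(dec, bi)
        try:
            h = hj.hjorth_features(coeffs)
        except Exception as exc:
            raise FeatureExtractionError(band_name, "hjorth", exc) from exc
        values += [h.activity, h.mobility, h.complexity]
        for feat, fn in (
            ("shannon", lambda c: ent.shannon_entropy(c, normalize=cfg.entropy.normalize_shannon)),
            ("sample", lambda c: ent.sample_entropy(c, cfg.entropy)),
            ("permutation", lambda c: ent.permutation_entropy(c, cfg.entropy)),
            ("dispersion", lambda c: ent.dispersion_entropy(c, cfg.entropy)),
            ("bubble", lambda c: ent.bubble_entropy(c, cfg.entropy)),
            ("slope", lambda c: ent.slope_entropy(c, cfg.entropy)),
        ):
            try:
                values.append(fn(coeffs))
            except Exception as exc:
                raise FeatureExtractionError(band_name, feat, exc) from exc
    names = tuple(f"{b}_{f}" for b in dec.band_names for f in FEATURE_KINDS)
    return FeatureVector(
        values=np.asarray(values),
        names=names,
        label=x.label,
        record_id=x.record_id,
        meta=cfg.to_dict(),
    )


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Records-by-features table with per-row class labels and shared metadata."""

    data: pd.DataFrame  # index: record ids, columns: feature names
    labels: pd.Series
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.data) != len(self.labels):
            raise ValueError("data/labels length mismatch")
        if self.data.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @classmethod
    def from_vectors(cls, vectors: list[FeatureVector]) -> "FeatureMatrix":
        if not vectors:
            raise ValueError("no feature vectors supplied")
        names = vectors[0].names
        meta = vectors[0].meta
        for v in vectors:
            if v.names != names or v.meta != meta:
                raise ValueError("all vectors must share names and metadata")
        ids = [v.record_id or f"rec{i}" for i, v in enumerate(vectors)]
        df = pd.DataFrame([v.values for v in vectors], index=ids, columns=list(names))
        return cls(df, pd.Series([v.label for v in vectors], index=ids), dict(meta))

    def subset(self, family: str) -> "FeatureMatrix":
        """Restrict columns to a feature family: hjorth (18), entropy (36) or all (54)."""
        if family == "all":
            cols = list(self.data.columns)
        elif family == "hjorth":
            cols = [c for c in self.data.columns if c.rsplit("_", 1)[1] in HJORTH_FEATURES]
        elif family == "entropy":
            cols = [c for c in self.data.columns if c.rsplit("_", 1)[1] in ent.ENTROPY_NAMES]
        else:
            raise ValueError(f"unknown family {family!r}; expected hjorth/entropy/all")
        return FeatureMatrix(self.data[cols].copy(), self.labels.copy(), dict(self.meta))

    def select_rows(self, idx) -> "FeatureMatrix":
        return FeatureMatrix(self.data.iloc[idx].copy(), self.labels.iloc[idx].copy(), dict(self.meta))

    # -- CSV round-trip -----------------------------------------------------
    def to_csv(self, path) -> None:
        """Header `#` comment lines carry the resolved config; then names + label."""
        with open(path, "w") as fh:
            fh.write(f"# ecgsubband feature matrix\n# meta: {json.dumps(self.meta, sort_keys=True)}\n")
            out = self.data.copy()
            out.insert(len(out.columns), "label", self.labels)
            out.to_csv(fh, index=True, index_label="record_id", float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        meta: dict = {}
        body = io.StringIO()
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    if line.startswith("# meta:"):
                        meta = json.loads(line[len("# meta:"):])
                else:
                    body.write(line)
        body.seek(0)
        df = pd.read_csv(body, index_col="record_id")
        df.index.name = None
        labels = df.pop("label")
        labels.name = None
        return cls(df, labels, meta)


def build_feature_matrix(
    records: list[ECGSignal], config: ExtractionConfig | None = None
) -> FeatureMatrix:
    """Extract features for every record; drop records whose entropy is undefined.

    Dropped records are logged with the band/feature/reason rather than
    imputed, so the matrix never contains missing values.
    """
    vectors = []
    for rec in records:
        try:
            vectors.append(extract_features(rec, config))
        except FeatureExtractionError as exc:
            if isinstance(exc.cause, UndefinedEntropyError):
                logger.warning("dropping record %s: %s", rec.record_id, exc)
            else:
                raise
    n_drop = len(records) - len(vectors)
    if n_drop:
        logger.warning("dropped %d/%d records with undefined entropies", n_drop, len(records))
    return FeatureMatrix.from_vectors(vectors)


# ---------------------------------------------------------------------------
# ANOVA screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    feature: str
    f_stat: float
    p_value: float
    group_means: dict  # class -> (mean, sd)
    significant: bool
    degenerate: bool = False


def anova_screen(
    fm: FeatureMatrix, alpha: float = 0.05, bonferroni: bool = False
) -> list[AnovaResult]:
    """One-way fixed-effects ANOVA per feature column across class groups.

    Raw p-values by default (an optional Bonferroni adjustment multiplies
    by the number of features). If every group has zero within-group
    variance the F ratio is degenerate: equal means report p = 1, unequal
    means p = 0, both flagged.
    """
    classes = sorted(set(fm.labels))
    if len(classes) < 2:
        raise ValueError("ANOVA needs at least 2 classes")
    for c in classes:
        if (fm.labels == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 rows")
    n_tests = len(fm.data.columns)
    results = []
    for col in fm.data.columns:
        groups = [fm.data.loc[fm.labels == c, col].to_numpy() for c in classes]
        gm = {c: (float(g.mean()), float(g.std(ddof=1))) for c, g in zip(classes, groups)}
        degenerate = all(np.ptp(g) == 0 for g in groups)
        if degenerate:
            means = [g.mean() for g in groups]
            p = 1.0 if np.ptp(means) == 0 else 0.0
            f = 0.0 if p == 1.0 else float("inf")
        else:
            f, p = (float(v) for v in stats.f_oneway(*groups))
        if bonferroni:
            p = min(1.0, p * n_tests)
        results.append(
            AnovaResult(col, f, p, gm, significant=bool(p < alpha), degenerate=degenerate)
        )
    return results


def anova_table(results: list[AnovaResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"feature": r.feature, "F": r.f_stat, "p": r.p_value,
               "significant": r.significant, "degenerate": r.degenerate}
        for c, (m, s) in r.group_means.items():
            row[f"{c}_mean"], row[f"{c}_sd"] = m, s
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")


def family_mean_features(fm: FeatureMatrix) -> FeatureMatrix:
    """Per-record mean of each feature kind across the six bands.

    Convenience view: one column per feature family name (activity,
    mobility, ..., slope) averaged over bands, clearly distinct from the
    per-band screen.
    """
    cols = {}
    for feat in FEATURE_KINDS:
        members = [c for c in fm.data.columns if c.rsplit("_", 1)[1] == feat]
        if members:
            cols[f"mean_{feat}"] = fm.data[members].mean(axis=1)
    return FeatureMatrix(pd.DataFrame(cols, index=fm.data.index), fm.labels.copy(), dict(fm.meta))
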