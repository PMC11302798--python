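"""End-to-end agreement analysis: ICC* screening, pairwise agreement maps,
class discovery, reference rating and the metric-comparison report.

The front door is :class:`AgreementStudy`, a model object built from a
:class:`~radicc.features.FeatureTable` (optionally with a per-pair geometric
metric table); ``fit()`` returns an :class:`AgreementResults` carrying the
per-feature ICC* estimates with confidence bounds, the screened feature
selection and the pairwise agreement maps, plus methods for clustering the
segmentations, rating them against a reference, and comparing ICC with
DSC/sDSC/HD.  The free functions underneath (``screen_features``,
``build_agreement_map``, ``discover_classes``, ``rate_against_reference``,
``metric_comparison_report``) are the same steps usable piecemeal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .agreement import (ICCResult, icc_star, pairwise_icc,
                        pairwise_icc_summary)
from .features import ExtractionConfig, FeatureId, FeatureTable, extract_cohort
from .metrics import (DEFAULT_SDSC_TOLERANCE_MM, metrics_to_frame,
                      pairwise_metrics)
from .volumes import Cohort

DEFAULT_BAND = (0.1, 0.51)
DEFAULT_N_SELECT = 10


# --------------------------------------------------------------------------
# Screening and selection


@dataclass
class SelectionReport:
    """ICC* screen of the panel and the selected low-agreement features."""

    icc_star: pd.DataFrame           # per feature: icc, lower, upper, degenerate
    band: tuple[float, float]
    in_band: list[FeatureId]
    selected: list[FeatureId]
    degenerate: list[FeatureId]
    selection_rule: str = "lowest-icc-star-in-band"

    def histogram(self, bins=20) -> tuple[np.ndarray, np.ndarray]:
        vals = self.icc_star.loc[~self.icc_star["degenerate"], "icc"].to_numpy()
        return np.histogram(vals, bins=bins)


def screen_features(table: FeatureTable, band: tuple[float, float] = DEFAULT_BAND,
                    n_select: int = DEFAULT_N_SELECT,
                    selected: Sequence[FeatureId] | None = None) -> SelectionReport:
    """Compute ICC* per feature and select low-agreement features.

    ``in_band`` are the non-degenerate features whose ICC* lies in
    ``[band[0], band[1]]``; the default rule picks the ``n_select`` lowest
    ICC* features inside the band.  Pass ``selected`` to force an explicit
    list (it is validated against the table but not against the band).
    """
    rows = {}
    degenerate = []
    for fid in table.feature_ids:
        res = icc_star(table, fid)
        rows[fid] = {"icc": res.icc, "lower": res.lower95, "upper": res.upper95,
                     "degenerate": res.degenerate}
        if res.degenerate:
            degenerate.append(fid)
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index = pd.MultiIndex.from_tuples(
        frame.index, names=["image_type", "feature_class", "feature_name"])
    lo, hi = band
    ok = ~frame["degenerate"]
    in_band_mask = ok & (frame["icc"] >= lo) & (frame["icc"] <= hi)
    in_band = [FeatureId(*t) for t in frame.index[in_band_mask]]
    if selected is not None:
        chosen = [FeatureId(*f) for f in selected]
        missing = set(chosen) - set(table.feature_ids)
        if missing:
            raise ValueError(f"selected features not in table: {sorted(missing)[:5]}")
        rule = "explicit-list"
    else:
        band_frame = frame[in_band_mask].sort_values("icc")
        chosen = [FeatureId(*t) for t in band_frame.index[:n_select]]
        rule = "lowest-icc-star-in-band"
        if not in_band:
            warnings.warn(f"no feature has ICC* inside the band {band}; "
                          "selection is empty", stacklevel=2)
    return SelectionReport(icc_star=frame, band=(float(lo), float(hi)),
                           in_band=in_band, selected=chosen,
                           degenerate=degenerate, selection_rule=rule)


# --------------------------------------------------------------------------
# Agreement maps and class discovery


@dataclass
class AgreementMap:
    """Pairwise-ICC matrices (k x k, diagonal 1) for the selected features."""

    per_feature: dict[FeatureId, pd.DataFrame]
    results: dict[FeatureId, dict[tuple[str, str], ICCResult]]
    segmentation_ids: list[str]

    @property
    def mean_matrix(self) -> pd.DataFrame:
        """Element-wise mean of the per-feature matrices (NaNs ignored)."""
        stack = np.stack([m.to_numpy() for m in self.per_feature.values()])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(stack, axis=0)
        ids = self.segmentation_ids
        return pd.DataFrame(mean, index=ids, columns=ids)

    def summary_row(self, feature: FeatureId) -> dict:
        mean, minimum = pairwise_icc_summary(self.results[feature])
        return {"icc_average": mean, "icc_min": minimum}


def build_agreement_map(table: FeatureTable,
                        selected: Iterable[FeatureId]) -> AgreementMap:
    """Fill one k x k symmetric pairwise-ICC matrix per selected feature.

    Degenerate pair ICCs become NaN cells (flagged by remaining NaN); the
    diagonal is 1 by convention.
    """
    selected = [FeatureId(*f) for f in selected]
    if not selected:
        raise ValueError("selected feature list is empty")
    ids = table.segmentation_ids
    per_feature, results = {}, {}
    for fid in selected:
        res = pairwise_icc(table, fid)
        mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
        for (i, j), r in res.items():
            val = np.nan if r.degenerate else r.icc
            mat.loc[i, j] = mat.loc[j, i] = val
        per_feature[fid] = mat
        results[fid] = res
    return AgreementMap(per_feature, results, list(ids))


def discover_classes(agreement: AgreementMap, n_classes: int = 3) -> dict[str, int]:
    """Cluster segmentations by average-linkage on distance 1 - mean ICC.

    ICC is floored at -1 (distance clamped to [0, 2]); NaN cells fall back
    to the maximal distance.  Deterministic given the map.  Returns
    segmentation-id -> class label (1..n_classes).
    """
    ids = agreement.segmentation_ids
    if n_classes > len(ids):
        raise ValueError(f"n_classes={n_classes} exceeds k={len(ids)}")
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    mean = agreement.mean_matrix.to_numpy(copy=True)
    mean = np.clip(mean, -1.0, 1.0)
    dist = 1.0 - mean
    dist[np.isnan(dist)] = 2.0
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    labels = fcluster(linkage(squareform(dist, checks=False), method="average"),
                      t=n_classes, criterion="maxclust")
    return dict(zip(ids, (int(l) for l in labels)))


def partitions_equal(a: dict[str, int], b: dict[str, int]) -> bool:
    """True when two labelings induce the same partition (labels renamed)."""
    if set(a) != set(b):
        return False
    ga = {}
    for key, lab in a.items():
        ga.setdefault(lab, set()).add(key)
    gb = {}
    for key, lab in b.items():
        gb.setdefault(lab, set()).add(key)
    return set(map(frozenset, ga.values())) == set(map(frozenset, gb.values()))


def class_recovery_experiment(selected: Iterable[FeatureId],
                              n_seeds: int = 100, base_seed: int = 1,
                              spec=None,
                              config: ExtractionConfig = ExtractionConfig()
                              ) -> float:
    """Fraction of phantom replicates whose planted families are recovered.

    For each replicate seed a fresh cohort is generated, the ``selected``
    features are extracted, the pairwise agreement map is built and
    clustered into as many classes as the generator planted; the run counts
    as recovered when the partition equals the planted family assignment.
    The feature selection is held fixed across replicates (it characterises
    the study design, not one realisation).
    """
    from dataclasses import replace

    from .phantoms import PhantomSpec, make_cohort

    spec = PhantomSpec() if spec is None else spec
    selected = [FeatureId(*f) for f in selected]
    hits = 0
    for i in range(n_seeds):
        cohort = make_cohort(replace(spec, seed=base_seed + i))
        families = cohort.provenance["families"]
        labels = {name: lab + 1
                  for lab, name in enumerate(dict.fromkeys(families.values()))}
        truth = {sid: labels[fam] for sid, fam in families.items()}
        table = extract_cohort(cohort, config, subset=selected)
        amap = build_agreement_map(table, selected)
        found = discover_classes(amap, n_classes=len(labels))
        hits += partitions_equal(found, truth)
    return hits / n_seeds


# --------------------------------------------------------------------------
# Reference-based rating


def rate_against_reference(table: FeatureTable, selected: Iterable[FeatureId],
                           reference_id: str, threshold: float = 0.5,
                           rule: str = "all") -> pd.DataFrame:
    """Rate every non-reference segmentation against a gold standard.

    For each selected feature and non-reference segmentation the pairwise
    ICC against ``reference_id`` is tabulated (rows = features, columns =
    ``icc<ref>-<other>``); a segmentation is "discordant" when all
    (``rule='all'``) or the median (``rule='median'``) of its ICCs falls
    below ``threshold``.  The verdicts sit in the ``verdict`` row.
    """
    if rule not in ("all", "median"):
        raise ValueError(f"unknown rating rule {rule!r}")
    ids = table.segmentation_ids
    if reference_id not in ids:
        raise ValueError(f"reference {reference_id!r} not among {ids}")
    selected = [FeatureId(*f) for f in selected]
    others = [s for s in ids if s != reference_id]
    cols = {s: {} for s in others}
    dropped = []
    for fid in selected:
        res = pairwise_icc(table, fid)
        for s in others:
            key = tuple(sorted((reference_id, s)))
            r = res[key]
            cols[s][fid] = np.nan if r.degenerate else r.icc
    frame = pd.DataFrame({f"icc{reference_id}-{s}": pd.Series(cols[s])
                          for s in others})
    frame.index = pd.MultiIndex.from_tuples(
        frame.index, names=["image_type", "feature_class", "feature_name"])
    if frame.isna().any().any():
        dropped = frame.index[frame.isna().any(axis=1)].tolist()
        warnings.warn(f"dropping {len(dropped)} feature(s) with degenerate "
                      f"reference ICC: {dropped[:3]}", stacklevel=2)
        frame = frame.dropna()
    verdicts = {}
    for s, col in zip(others, frame.columns):
        vals = frame[col].to_numpy()
        if len(vals) == 0:
            verdicts[col] = "undecided"
        elif rule == "all":
            verdicts[col] = "discordant" if (vals < threshold).all() else "concordant"
        else:
            verdicts[col] = ("discordant" if np.median(vals) < threshold
                             else "concordant")
    frame.attrs["verdicts"] = verdicts
    frame.attrs["threshold"] = threshold
    frame.attrs["rule"] = rule
    return frame


# --------------------------------------------------------------------------
# Metric comparison report


@dataclass
class MetricComparisonReport:
    """ICC-vs-geometry comparison over the shared segmentation pairs."""

    scatter: pd.DataFrame      # per (feature, pair): icc + tumor-averaged metrics
    pair_means: pd.DataFrame   # per pair: tumor-averaged dsc/sdsc/hd
    per_pair_distribution: pd.DataFrame  # per pair: metric quartiles over tumors
    summary: dict


def metric_comparison_report(agreement: AgreementMap,
                             metrics: pd.DataFrame) -> MetricComparisonReport:
    """Join per-pair ICC values with tumor-averaged DSC/sDSC/HD.

    ``metrics`` is the tidy per-pair table from
    :func:`radicc.metrics.metrics_to_frame` covering the same pair set as
    the agreement map (all tumors).
    """
    need = {"tumor_id", "seg_i", "seg_j", "dsc", "sdsc", "hd_mm"}
    if not need <= set(metrics.columns):
        raise ValueError(f"metric table missing columns {sorted(need - set(metrics.columns))}")
    metrics = metrics.copy()
    metrics["pair"] = [tuple(sorted((str(i), str(j))))
                       for i, j in zip(metrics["seg_i"], metrics["seg_j"])]
    map_pairs = {tuple(sorted(p))
                 for p in next(iter(agreement.results.values()))}
    missing = map_pairs - set(metrics["pair"])
    if missing:
        raise ValueError(f"metric table lacks pairs {sorted(missing)[:5]}")

    pair_means = (metrics.groupby("pair")[["dsc", "sdsc", "hd_mm"]]
                  .mean().loc[sorted(map_pairs)])
    dist = (metrics.groupby("pair")[["dsc", "sdsc", "hd_mm"]]
            .agg(["min", "median", "mean", "max", "std"]).loc[sorted(map_pairs)])

    rows = []
    for fid, res in agreement.results.items():
        for pair, r in res.items():
            pair = tuple(sorted(pair))
            rows.append({
                "image_type": fid.image_type, "feature_class": fid.feature_class,
                "feature_name": fid.feature_name,
                "seg_i": pair[0], "seg_j": pair[1],
                "icc": np.nan if r.degenerate else r.icc,
                "dsc": pair_means.loc[[pair], "dsc"].iloc[0],
                "sdsc": pair_means.loc[[pair], "sdsc"].iloc[0],
                "hd_mm": pair_means.loc[[pair], "hd_mm"].iloc[0],
            })
    scatter = pd.DataFrame(rows)
    icc_by_feature = scatter.groupby(
        ["image_type", "feature_class", "feature_name"])["icc"]
    summary = {
        "icc_min_per_feature": icc_by_feature.min().to_dict(),
        "icc_max_per_feature": icc_by_feature.max().to_dict(),
        "icc_range": float(np.nanmax(scatter["icc"]) - np.nanmin(scatter["icc"])),
        "dsc_min": float(pair_means["dsc"].min()),
        "dsc_range": float(pair_means["dsc"].max() - pair_means["dsc"].min()),
        "sdsc_min": float(pair_means["sdsc"].min()),
        "hd_max_mm": float(pair_means["hd_mm"].max()),
        "n_pairs": len(pair_means),
    }
    pm = pair_means.reset_index()
    pm[["seg_i", "seg_j"]] = pd.DataFrame(pm["pair"].tolist(), index=pm.index)
    return MetricComparisonReport(scatter=scatter,
                                  pair_means=pm.drop(columns="pair"),
                                  per_pair_distribution=dist, summary=summary)


# --------------------------------------------------------------------------
# The model / results front end


class AgreementStudy:
    """Radiomics-agreement model over a cohort feature table.

    Parameters
    ----------
    table:
        Rectangular tumors x segmentations feature table.
    pair_metrics:
        Optional tidy per-pair DSC/sDSC/HD table (one row per tumor and
        unordered pair) for the metric-comparison report.
    band, n_select, selected:
        ICC* screening band, selection size, or an explicit feature list
        overriding the default lowest-ICC*-in-band rule.
    """

    def __init__(self, table: FeatureTable, pair_metrics: pd.DataFrame | None = None,
                 band: tuple[float, float] = DEFAULT_BAND,
                 n_select: int = DEFAULT_N_SELECT,
                 selected: Sequence[FeatureId] | None = None):
        self.table = table
        self.pair_metrics = pair_metrics
        self.band = band
        self.n_select = n_select
        self.selected = selected

    @classmethod
    def from_cohort(cls, cohort: Cohort, config: ExtractionConfig = ExtractionConfig(),
                    tolerance_mm: float = DEFAULT_SDSC_TOLERANCE_MM,
                    **kwargs) -> "AgreementStudy":
        """Extract the full panel and pairwise metrics, then build the model.

        Metrics are computed on the resampled grid, consistent with feature
        extraction.
        """
        from .filtering import resample_mask
        table = extract_cohort(cohort, config)
        rows = []
        for entry in cohort.tumors:
            rmasks = {sid: resample_mask(m, config.filters)
                      for sid, m in entry.segmentations.items()}
            rows.extend(pairwise_metrics(rmasks, entry.tumor_id, tolerance_mm))
        return cls(table, metrics_to_frame(rows), **kwargs)

    def fit(self) -> "AgreementResults":
        selection = screen_features(self.table, self.band, self.n_select,
                                    self.selected)
        agreement = (build_agreement_map(self.table, selection.selected)
                     if selection.selected else None)
        return AgreementResults(self, selection, agreement)


class AgreementResults:
    """Fitted agreement analysis: estimates, selection and agreement maps."""

    def __init__(self, model: AgreementStudy, selection: SelectionReport,
                 agreement: AgreementMap | None):
        self.model = model
        self.selection = selection
        self.agreement = agreement

    # -- tabular views ------------------------------------------------------

    @property
    def icc_star_table(self) -> pd.DataFrame:
        return self.selection.icc_star

    def selected_table(self) -> pd.DataFrame:
        """Per selected feature: ICC* with bounds plus pairwise mean/min."""
        if self.agreement is None:
            return pd.DataFrame()
        rows = []
        for fid in self.selection.selected:
            star = self.selection.icc_star.loc[tuple(fid)]
            extra = self.agreement.summary_row(fid)
            rows.append({"image_type": fid.image_type,
                         "feature_class": fid.feature_class,
                         "feature_name": fid.feature_name,
                         "icc_star": star["icc"],
                         "icc_average": extra["icc_average"],
                         "icc_min": extra["icc_min"],
                         "lower": star["lower"], "upper": star["upper"]})
        return pd.DataFrame(rows)

    # -- analysis methods ---------------------------------------------------

    def discover_classes(self, n_classes: int = 3) -> dict[str, int]:
        if self.agreement is None:
            raise ValueError("no selected features; cannot cluster")
        return discover_classes(self.agreement, n_classes)

    def rate_against_reference(self, reference_id: str, threshold: float = 0.5,
                               rule: str = "all") -> pd.DataFrame:
        return rate_against_reference(self.model.table, self.selection.selected,
                                      reference_id, threshold, rule)

    def metric_comparison(self) -> MetricComparisonReport:
        if self.model.pair_metrics is None:
            raise ValueError("model was built without a pair-metric table")
        if self.agreement is None:
            raise ValueError("no selected features; nothing to compare")
        return metric_comparison_report(self.agreement, self.model.pair_metrics)

    # -- summary ------------------------------------------------------------

    def summary(self) -> str:
        tab = self.selection.icc_star
        ok = tab.loc[~tab["degenerate"], "icc"]
        lines = [
            "Radiomics segmentation-agreement analysis",
            "=" * 57,
            f"tumors: {len(self.model.table.tumor_ids)}   "
            f"segmentations: {len(self.model.table.segmentation_ids)}   "
            f"features: {len(self.model.table.feature_ids)}",
            f"ICC model: A-1 two-way mixed, absolute agreement",
            f"ICC* range: [{ok.min():.3f}, {ok.max():.3f}]  "
            f"(degenerate: {len(self.selection.degenerate)})",
            f"screening band: [{self.selection.band[0]:g}, {self.selection.band[1]:g}]"
            f"  in band: {len(self.selection.in_band)}   "
            f"selected: {len(self.selection.selected)}",
        ]
        sel = self.selected_table()
        if len(sel):
            lines.append("")
            lines.append(sel.round(3).to_string(index=False))
        return "\n".join(lines)

    # -- plots (optional; require matplotlib) --------------------------------

    def plot_heatmap(self, feature: FeatureId, ax=None):
        """Heat map of one selected feature's pairwise-ICC matrix."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        mat = self.agreement.per_feature[FeatureId(*feature)]
        im = ax.imshow(mat.to_numpy(), vmin=-0.2, vmax=1.0, cmap="viridis")
        ax.set_xticks(range(len(mat)), mat.columns, rotation=90)
        ax.set_yticks(range(len(mat)), mat.index)
        ax.set_title(" ".join(feature))
        ax.figure.colorbar(im, ax=ax, label="ICC")
        return ax

    def plot_metric_scatter(self, metric: str = "dsc", ax=None):
        """ICC (abscissa) vs a geometric metric (ordinate) per pair."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        rep = self.metric_comparison()
        for name, grp in rep.scatter.groupby("feature_name"):
            ax.scatter(grp["icc"], grp[metric], s=12, label=name, alpha=0.7)
        ax.set_xlabel("pairwise ICC")
        ax.set_ylabel(metric)
        ax.legend(fontsize=6)
        return ax
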