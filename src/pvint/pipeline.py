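"""End-to-end orchestration: synthesize -> extract -> classify -> report.

A run is driven by a :class:`RunConfig`; every output directory receives a
``manifest.json`` recording the package version, the full configuration,
its hash and the seed, so a rerun with the same config reproduces the same
outputs bit-for-bit (all stage randomness derives from the one seed via
stable per-stage child seeds).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core import derive_seed
from .classify import SubtypeModel, fisher_exact_rc
from .features import extract_all, features_dataframe
from .synth import NOISE_V_SD, iter_cohort

log = logging.getLogger("pvint")


@dataclass
class RunConfig:
    """Configuration of a full synthetic-cohort analysis run."""

    genotypes: list = field(default_factory=lambda: ["WT"])
    seed: int = 0
    k: int | None = None
    k_range: tuple = (2, 8)
    n_restarts: int = 100
    gap_veto: bool = True
    noise_v: float = NOISE_V_SD
    pool_genotypes: bool = True   # cluster all genotypes together
    fisher_pair: tuple | None = None  # e.g. ("WT", "GlobalLis")
    out_dir: str = "pvint_run"
    features_csv: str | None = None   # skip synthesis, classify this table
    max_cells_per_subtype: int | None = None  # downscale cohorts (testing)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        cfg = cls(**data)
        if cfg.features_csv is None and not cfg.genotypes:
            raise ValueError("config needs genotypes or features_csv")
        if cfg.features_csv is not None and not Path(cfg.features_csv).exists():
            raise ValueError(f"features_csv {cfg.features_csv!r} does not exist")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def synthesize_features(genotypes, seed: int, noise_v: float = NOISE_V_SD,
                        keep_recordings: bool = False,
                        max_cells_per_subtype: int | None = None):
    """Simulate cohorts and extract features, streaming cell by cell.

    Returns (features DataFrame with a ``true_label`` column,
    recordings list or None).
    """
    from .synth import COHORT_COMPOSITION, SUBTYPE_TABLE

    records, true_labels, recs = [], [], []
    for g in genotypes:
        params = None
        if max_cells_per_subtype is not None:
            params = [SUBTYPE_TABLE[(g, st)].with_n_cells(
                          min(n, max_cells_per_subtype))
                      for st, n in COHORT_COMPOSITION[g].items()]
        for rec, label, spec in iter_cohort(g, params,
                                            seed=derive_seed(seed, f"synth:{g}"),
                                            noise_v=noise_v):
            feats = extract_all(rec)
            if feats.nulls:
                log.warning("cell %s: null features %s", rec.cell_id,
                            sorted(feats.nulls))
            records.append(feats)
            true_labels.append(label)
            if keep_recordings:
                recs.append(rec)
    df = features_dataframe(records)
    df["true_label"] = true_labels
    return df, (recs if keep_recordings else None)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "outputs": {},
    }

    if config.features_csv is not None:
        df = pd.read_csv(config.features_csv, index_col=0)
    else:
        df, _ = synthesize_features(
            config.genotypes, config.seed, config.noise_v,
            max_cells_per_subtype=config.max_cells_per_subtype)
    fpath = out / "features.csv"
    df.to_csv(fpath)
    manifest["outputs"]["features"] = fpath.name

    model = SubtypeModel(df, k=config.k, k_range=tuple(config.k_range),
                         n_restarts=config.n_restarts,
                         gap_veto=config.gap_veto)
    res = model.fit(seed=derive_seed(config.seed, "classify"))

    labels = pd.DataFrame({"subtype": res.labels,
                           "raw_cluster": res.raw_labels,
                           "silhouette": res.silhouette_values,
                           "PC1": res.pca_coords["PC1"],
                           "PC2": res.pca_coords["PC2"]})
    if "true_label" in df.columns:
        labels["true_label"] = df.loc[labels.index, "true_label"]
    lpath = out / "labels.csv"
    labels.to_csv(lpath)
    manifest["outputs"]["labels"] = lpath.name

    tab = res.composition()
    comp = pd.DataFrame(tab.counts, index=tab.genotypes, columns=tab.subtypes)
    comp_pct = pd.DataFrame(tab.percentages(), index=tab.genotypes,
                            columns=tab.subtypes)
    cpath = out / "composition.csv"
    pd.concat({"count": comp, "percent": comp_pct}, axis=1).to_csv(cpath)
    manifest["outputs"]["composition"] = cpath.name

    diagnostics = {
        "chosen_k": res.chosen_k,
        "votes": res.votes,
        "ward_agreement": res.ward_agreement,
        "mean_silhouette": float(res.silhouette_values.mean()),
        "excluded_cells": list(map(str, model.excluded)),
    }
    if config.fisher_pair is not None:
        p, method = res.fisher_test(*config.fisher_pair)
        diagnostics["fisher"] = {"pair": list(config.fisher_pair),
                                 "p_value": p, "method": method}
    elif len(comp.index) >= 2:
        p, method = res.fisher_test(comp.index[0], comp.index[1])
        diagnostics["fisher"] = {"pair": list(comp.index[:2]),
                                 "p_value": p, "method": method}
    dpath = out / "diagnostics.json"
    dpath.write_text(json.dumps(diagnostics, indent=1, default=float))
    manifest["outputs"]["diagnostics"] = dpath.name

    rpath = out / "summary.txt"
    rpath.write_text(report(df, res))
    manifest["outputs"]["summary"] = rpath.name

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    return manifest


_TABLE_ROWS = [
    ("rin", "Input resistance (MOhm)"),
    ("rheobase", "Rheobase (pA)"),
    ("ff_2x", "Firing Freq 2x Threshold (Hz)"),
    ("ar_2x", "Adaptation Ratio 2x Threshold"),
    ("ff_3x", "Firing Freq 3x Threshold (Hz)"),
    ("ar_3x", "Adaptation Ratio 3x Threshold"),
    ("ap_threshold", "AP Threshold (mV)"),
    ("ap_halfwidth", "AP Half-width (ms)"),
    ("ap_amplitude", "AP Amplitude (mV)"),
    ("max_rise", "AP Max Rise Slope (mV/ms)"),
    ("max_decay", "AP Max Decay Slope (mV/ms)"),
    ("ahp_amplitude", "AHP Amplitude (mV)"),
    ("tau_m", "Membrane Time Constant (ms)"),
    ("cm", "Membrane Capacitance (pF)"),
    ("sag_index", "Sag Index"),
]


def report(features: pd.DataFrame, results) -> str:
    """Per-genotype, per-subtype mean +/- SEM table plus the fit summary."""
    df = features.copy()
    df = df.loc[results.labels.index]
    df["subtype"] = results.labels
    cols = []
    header = []
    for (g, st), grp in df.groupby(["genotype", "subtype"], sort=True):
        header.append(f"{g} {st} ({len(grp)} cells)")
        col = []
        for key, _ in _TABLE_ROWS:
            if key not in grp.columns or grp[key].dropna().empty:
                col.append("n/a")
                continue
            m = grp[key].mean()
            s = grp[key].sem() if len(grp) > 1 else float("nan")
            col.append(f"{m:.4g} ± {s:.2g}" if s == s else f"{m:.4g}")
        cols.append(col)
    table = pd.DataFrame(dict(zip(header, cols)),
                         index=[name for _, name in _TABLE_ROWS])
    return table.to_string() + "\n\n" + results.summary()
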