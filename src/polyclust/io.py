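"""Readers and writers for the on-disk formats.

Formats
-------
* final report — GenomeStudio-style tab-delimited long export: an optional
  bracketed header block terminated by a ``[Data]`` line, then one row per
  (marker, sample) with either polar (Theta, R) or raw channel (X, Y)
  intensities.  Raw channels are converted by theta = (2/pi)·arctan2(Y, X),
  R = X + Y.
* intensity matrices — wide TSV, markers x samples, one file per channel.
* genotype matrices — wide TSV of calls, or long TSV with confidences
  (lossless round trip), or a minimal VCF 4.2 export of the biallelic
  assays.
* cluster file — versioned JSON serialisation of a fitted
  :class:`~polyclust.calling.ClusterModel`; lossless because the model
  itself is quantised to 6 decimals.
* simulator / run configuration — YAML.

All writers emit fixed 6-decimal floats and lexicographically ordered rows
so identical inputs give byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .calling import NC, ClusterInfo, ClusterModel, GenotypeMatrix
from .panel import IntensityPanel, theta_r_from_xy
from .signal_sim import AssayDesign, Founder, NoiseModel, PopulationDesign, TruthSet

__all__ = [
    "read_final_report",
    "write_final_report",
    "read_panel_matrices",
    "write_panel_matrices",
    "write_genotypes",
    "read_genotypes_long",
    "write_cluster_file",
    "read_cluster_file",
    "write_truth",
    "read_truth",
    "load_sim_config",
]

CLUSTER_FILE_VERSION = 1

#: default column-name map for final reports; override for other dialects
DEFAULT_COLUMNS = {
    "marker": "SNP Name",
    "sample": "Sample ID",
    "theta": "Theta",
    "r": "R",
    "x": "X",
    "y": "Y",
    "population": "Population",
}


def _fmt(x: float) -> str:
    return f"{x:.6f}"


# ---------------------------------------------------------------------------
# final report
# ---------------------------------------------------------------------------


def read_final_report(
    path, columns: Mapping[str, str] | None = None
) -> IntensityPanel:
    """Parse a final-report-style long TSV into an :class:`IntensityPanel`.

    Requires marker and sample columns plus either (Theta, R) or (X, Y);
    raw channels are converted to polar form.  Duplicate (marker, sample)
    rows, missing required columns, out-of-range theta and non-numeric
    intensities are errors, with offending line numbers where possible.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    path = Path(path)
    skip = 0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("["):
            skip = 1
            for line in fh:
                skip += 1
                if line.strip() == "[Data]":
                    break
            else:
                raise ValueError(f"{path}: header block without a [Data] line")
    df = pd.read_csv(path, sep="\t", skiprows=skip, dtype=str)

    for key in ("marker", "sample"):
        if cols[key] not in df.columns:
            raise ValueError(f"{path}: missing required column {cols[key]!r}")
    polar = cols["theta"] in df.columns and cols["r"] in df.columns
    raw = cols["x"] in df.columns and cols["y"] in df.columns
    if not polar and not raw:
        raise ValueError(
            f"{path}: need either ({cols['theta']}, {cols['r']}) or "
            f"({cols['x']}, {cols['y']}) columns"
        )

    value_cols = [cols["theta"], cols["r"]] if polar else [cols["x"], cols["y"]]
    parsed = {}
    for col in value_cols:
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + skip + 2  # 1-based with header line
            raise ValueError(f"{path}: non-numeric {col!r} value at line {line}")
        parsed[col] = num

    dup = df.duplicated(subset=[cols["marker"], cols["sample"]])
    if dup.any():
        pair = df.loc[dup.idxmax(), [cols["marker"], cols["sample"]]].tolist()
        raise ValueError(f"{path}: duplicate (marker, sample) row {tuple(pair)}")

    if polar:
        theta, r = parsed[cols["theta"]], parsed[cols["r"]]
        if ((theta < 0) | (theta > 1)).any():
            raise ValueError(f"{path}: theta outside [0, 1]")
    else:
        theta, r = theta_r_from_xy(parsed[cols["x"]], parsed[cols["y"]])
        theta, r = pd.Series(theta, index=df.index), pd.Series(r, index=df.index)

    long = pd.DataFrame(
        {
            "marker": df[cols["marker"]],
            "sample": df[cols["sample"]],
            "theta": theta,
            "r": r,
        }
    )
    theta_w = long.pivot(index="marker", columns="sample", values="theta").sort_index()
    r_w = long.pivot(index="marker", columns="sample", values="r").sort_index()
    theta_w = theta_w.sort_index(axis=1)
    r_w = r_w.sort_index(axis=1)

    samples = None
    if cols["population"] in df.columns:
        meta = (
            df[[cols["sample"], cols["population"]]]
            .drop_duplicates(cols["sample"])
            .set_index(cols["sample"])
            .rename(columns={cols["population"]: "population"})
        )
        samples = meta.reindex(theta_w.columns)
    return IntensityPanel(theta=theta_w, r=r_w, samples=samples)


def write_final_report(panel: IntensityPanel, path, header: bool = True) -> None:
    """Write a panel as a final-report-style long TSV (deterministic order)."""
    path = Path(path)
    markers = sorted(map(str, panel.markers))
    samples = sorted(map(str, panel.sample_ids))
    with open(path, "w") as fh:
        if header:
            fh.write("[Header]\nContent\tpolyclust export\n[Data]\n")
        fh.write("SNP Name\tSample ID\tTheta\tR\tPopulation\n")
        for m in markers:
            for s in samples:
                th = panel.theta.at[m, s]
                rr = panel.r.at[m, s]
                if pd.isna(th) or pd.isna(rr):
                    continue
                pop = panel.samples.at[s, "population"]
                fh.write(f"{m}\t{s}\t{_fmt(th)}\t{_fmt(rr)}\t{pop}\n")


def write_panel_matrices(panel: IntensityPanel, prefix) -> None:
    """Write theta/R wide matrices and sample metadata as TSVs."""
    prefix = Path(prefix)
    panel.theta.sort_index().sort_index(axis=1).to_csv(
        f"{prefix}.theta.tsv", sep="\t", float_format="%.6f"
    )
    panel.r.sort_index().sort_index(axis=1).to_csv(
        f"{prefix}.r.tsv", sep="\t", float_format="%.6f"
    )
    panel.samples.sort_index().to_csv(f"{prefix}.samples.tsv", sep="\t")


def read_panel_matrices(prefix) -> IntensityPanel:
    prefix = Path(prefix)
    theta = pd.read_csv(f"{prefix}.theta.tsv", sep="\t", index_col=0)
    r = pd.read_csv(f"{prefix}.r.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(f"{prefix}.samples.tsv", sep="\t", index_col=0)
    return IntensityPanel(theta=theta, r=r, samples=samples)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def write_genotypes(
    matrix: GenotypeMatrix,
    path,
    format: str = "tsv_long",
    model: ClusterModel | None = None,
) -> None:
    """Write genotype calls as wide TSV, long TSV or VCF.

    The long TSV (marker, sample, call, cluster, confidence) round-trips
    losslessly through :func:`read_genotypes_long`.  VCF export keeps only
    assays with biallelic genotype labels, encoding AA->0/0, AB->0/1,
    BB->1/1 and anything else (NC, NULL) as ./.; markers whose model also
    carries a null-flagged cluster get FILTER=NULL_ALLELE (``model``
    required for that annotation).
    """
    path = Path(path)
    m = matrix.sorted()
    if format == "tsv_long":
        out = m.frame.copy()
        out["confidence"] = out["confidence"].map(_fmt)
        out.to_csv(path, sep="\t", index=False)
    elif format == "tsv_wide":
        m.wide("call").to_csv(path, sep="\t")
    elif format == "vcf":
        _write_vcf(m, path, model)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def read_genotypes_long(path) -> GenotypeMatrix:
    # keep_default_na: the literal call label "NULL" must survive parsing
    df = pd.read_csv(
        path, sep="\t", keep_default_na=False,
        dtype={"marker": str, "sample": str, "call": str, "cluster": str},
    )
    df["confidence"] = pd.to_numeric(df["confidence"])
    return GenotypeMatrix(df).sorted()


_VCF_CODE = {"AA": "0/0", "AB": "0/1", "BB": "1/1"}


def _write_vcf(matrix: GenotypeMatrix, path, model: ClusterModel | None) -> None:
    wide = matrix.wide("call")
    biallelic = [
        mk
        for mk in wide.index
        if set(wide.loc[mk].unique()) & set(_VCF_CODE)
    ]
    samples = list(wide.columns)
    n_skipped = len(wide.index) - len(biallelic)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FILTER=<ID=NULL_ALLELE,Description="Assay carries a low-intensity null-allele cluster">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##polyclust_skipped_non_biallelic={n_skipped}\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for pos, mk in enumerate(biallelic, start=1):
            filt = "PASS"
            if model is not None and mk in model and any(
                c.null for c in model.markers[mk]
            ):
                filt = "NULL_ALLELE"
            row = [str(mk), str(pos), str(mk), "A", "B", ".", filt, ".", "GT"]
            row += [_VCF_CODE.get(v, "./.") for v in wide.loc[mk]]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# cluster file
# ---------------------------------------------------------------------------


def write_cluster_file(model: ClusterModel, path) -> None:
    """Serialise a cluster model to versioned JSON (sorted, 6-decimal)."""
    payload = {
        "format": "polyclust-cluster-file",
        "version": model.version,
        "markers": {
            marker: [
                {
                    "ordinal": c.ordinal,
                    "center_theta": c.center_theta,
                    "center_r": c.center_r,
                    "spread_theta": c.spread_theta,
                    "spread_r": c.spread_r,
                    "n": c.n,
                    "null": bool(c.null),
                    "genotype": c.genotype,
                }
                for c in clusters
            ]
            for marker, clusters in sorted(model.markers.items())
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_cluster_file(path) -> ClusterModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "polyclust-cluster-file":
        raise ValueError(f"{path}: not a cluster file")
    version = payload.get("version")
    if version != CLUSTER_FILE_VERSION:
        raise ValueError(
            f"{path}: unsupported cluster-file version {version!r} "
            f"(expected {CLUSTER_FILE_VERSION})"
        )
    model = ClusterModel(version=version)
    for marker, clusters in payload["markers"].items():
        model.markers[marker] = [
            ClusterInfo(
                ordinal=c["ordinal"],
                center_theta=float(c["center_theta"]),
                center_r=float(c["center_r"]),
                spread_theta=float(c["spread_theta"]),
                spread_r=float(c["spread_r"]),
                n=int(c["n"]),
                null=bool(c["null"]),
                genotype=c["genotype"],
            )
            for c in clusters
        ]
    return model


# ---------------------------------------------------------------------------
# truth + simulator config
# ---------------------------------------------------------------------------


def write_truth(truth: TruthSet, path) -> None:
    out = truth.frame.sort_values(["marker", "sample"], kind="mergesort").copy()
    for col in ("x_dose", "y_dose"):
        out[col] = out[col].map(_fmt)
    out.to_csv(path, sep="\t", index=False)


def read_truth(path) -> TruthSet:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "sample": str})
    df["null"] = df["null"].astype(bool)
    return TruthSet(df)


def load_sim_config(path):
    """Build simulator objects from a YAML config.

    Layout::

        seed: 7
        noise: {theta_sd: 0.02, r_cv: 0.1, r_baseline: 0.08}
        markers:
          - marker_id: SNP1
            n_hyb_sites: 2
            target_site_index: 0
            fixed_alleles: {1: A}
            failure_sites: [1]
            failure_freq: 0.3
        populations:
          - pop_id: DIV
            kind: diversity
            n_samples: 200
            allele_freq: 0.4
          - pop_id: DH1
            kind: DH
            n_samples: 100
            parents:
              SNP1: [{allele: A}, {allele: B, failed_sites: [1]}]

    Returns (designs, populations, noise, seed).
    """
    cfg = yaml.safe_load(Path(path).read_text())
    designs = []
    for d in cfg.get("markers", []):
        d = dict(d)
        if "fixed_alleles" in d:
            d["fixed_alleles"] = {int(k): v for k, v in d["fixed_alleles"].items()}
        if "failure_sites" in d:
            d["failure_sites"] = tuple(d["failure_sites"])
        if "site_weights" in d and d["site_weights"] is not None:
            d["site_weights"] = tuple(d["site_weights"])
        designs.append(AssayDesign(**d))
    pops = []
    for p in cfg.get("populations", []):
        p = dict(p)
        if p.get("parents"):
            p["parents"] = {
                mk: tuple(
                    Founder(
                        allele=f.get("allele", "A"),
                        failed_sites=frozenset(f.get("failed_sites", [])),
                    )
                    for f in pair
                )
                for mk, pair in p["parents"].items()
            }
        pops.append(PopulationDesign(**p))
    noise = NoiseModel(**cfg.get("noise", {}))
    seed = int(cfg.get("seed", noise.seed))
    return designs, pops, noise, seed
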