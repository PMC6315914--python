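"""End-to-end pipeline: simulate/load -> filter -> diversity -> share -> ancestry.

A single flat YAML config drives a reproducible run: every output TSV
carries a header comment naming the config hash and seed, and rerunning
with an identical config reproduces the outputs byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestry import pca_projection, supervised_q
from .annotate import annotate_sites, read_gene_models
from .diversity import (
    RarefactionSpec,
    compare_groups,
    het_stats,
    max_feasible_g,
    pairwise_fst,
    rarefied_richness,
)
from .filters import FilterReport, filter_sites, ld_prune, one_snp_per_locus
from .genotypes import (
    MISSING,
    allele_frequencies,
    read_popmap,
    read_vcf,
    write_popmap,
    write_vcf,
)
from .sharing import (
    focal_unique_alleles,
    ibs_matrix,
    shared_private_report,
    shared_private_richness,
)
from .simulate import FocalSpec, GroupSpec, SimConfig, simulate_panel

logger = logging.getLogger(__name__)

DEFAULTS: dict = {
    "seed": 0,
    "stages": {
        "filter": True,
        "ld_prune": True,
        "single_snp_per_locus": False,
        "diversity": True,
        "share": True,
        "ancestry": True,
        "pca": True,
    },
    "filter": {"max_missing": 0.10, "min_maf": 0.01},
    "ld": {"window": 50, "step": 5, "r2_max": 0.5},
    "diversity": {"g": 18, "tolerance": 0.10},
    # share.g None -> auto: the largest g feasible for every group at the tolerance
    "share": {"g": None, "tolerance": 0.15, "bin_width": 0.10, "global_denominator": False},
    "ancestry": {"epsilon": 0.001, "ref_a": None, "ref_b": None},
    "annotation": {"promoter_window": 2000},
}


@dataclass
class RunConfig:
    """Flat pipeline configuration; unspecified keys take study defaults."""

    vcf: str | None = None
    popmap: str | None = None
    gene_models: str | None = None
    simulate: dict | None = None
    out_dir: str = "run"
    options: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {"vcf", "popmap", "gene_models", "simulate", "out_dir"}
        options = _merge(DEFAULTS, {k: v for k, v in raw.items() if k not in known})
        return cls(
            vcf=raw.get("vcf"),
            popmap=raw.get("popmap"),
            gene_models=raw.get("gene_models"),
            simulate=raw.get("simulate"),
            out_dir=raw.get("out_dir", "run"),
            options=options,
        )

    def hash(self) -> str:
        blob = json.dumps(
            {
                "vcf": self.vcf,
                "popmap": self.popmap,
                "gene_models": self.gene_models,
                "simulate": self.simulate,
                "options": self.options,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _merge(base: dict, override: dict) -> dict:
    out = {}
    for k, v in base.items():
        if isinstance(v, dict):
            out[k] = _merge(v, override.get(k, {}) if isinstance(override.get(k), dict) else {})
        else:
            out[k] = override.get(k, v)
    for k, v in override.items():
        if k not in out:
            out[k] = v
    return out


def _sim_config_from_block(block: dict, seed: int) -> SimConfig:
    groups = [GroupSpec(g["name"], int(g["n"]), float(g["F"])) for g in block["groups"]]
    focals = [
        FocalSpec(f["name"], f["source_a"], f["source_b"], float(f["q"]))
        for f in block.get("focals", [])
    ]
    law = block.get("ancestral_freq_law", ["uniform", 0.05, 0.95])
    return SimConfig(
        n_loci=int(block.get("n_loci", 7000)),
        group_specs=groups,
        focal_specs=focals,
        ancestral_freq_law=tuple(law),
        missing_rate=float(block.get("missing_rate", 0.0)),
        seed=int(block.get("seed", seed)),
    )


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ghostalleles {__version__} config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages; returns the run directory."""
    opts = config.options
    seed = int(opts["seed"])
    chash = config.hash()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        if config.simulate is not None:
            sim = _sim_config_from_block(config.simulate, seed)
            G, popmap, truth = simulate_panel(sim)
            write_vcf(G, str(out / "simulated.vcf"))
            write_popmap(popmap, str(out / "simulated.popmap.tsv"))
            truth_rows = [
                {"kind": "q", "name": k, "value": v} for k, v in truth["q"].items()
            ] + [{"kind": "F", "name": k, "value": v} for k, v in truth["F"].items()]
            _write_tsv(pd.DataFrame(truth_rows), out / "truth.tsv", chash, seed)
        else:
            if not config.vcf or not config.popmap:
                raise ValueError("config needs either a simulate block or vcf + popmap paths")
            G = read_vcf(config.vcf)
            popmap = read_popmap(config.popmap, samples=G.samples)
            mapped = set(popmap.assignments) | set(popmap.focal_samples)
            G = G.subset_samples([s for s in G.samples if s in mapped])

        if config.gene_models:
            stage = "annotation"
            models = read_gene_models(config.gene_models)
            classes = annotate_sites(
                G.sites, models, promoter_window=int(opts["annotation"]["promoter_window"])
            )
            G = G.with_annotations(classes)

        report = FilterReport()
        if opts["stages"]["filter"]:
            stage = "filter"
            G, report = filter_sites(
                G,
                max_missing=float(opts["filter"]["max_missing"]),
                min_maf=float(opts["filter"]["min_maf"]),
                report=report,
            )
        if opts["stages"]["single_snp_per_locus"]:
            stage = "single_snp_per_locus"
            n_in = G.n_sites
            G = one_snp_per_locus(G)
            report.add("one_snp_per_locus", {}, n_in, G.n_sites)
        if opts["stages"]["ld_prune"]:
            stage = "ld_prune"
            G, report = ld_prune(
                G,
                window=int(opts["ld"]["window"]),
                step=int(opts["ld"]["step"]),
                r2_max=float(opts["ld"]["r2_max"]),
                report=report,
            )
        if report.stages:
            _write_tsv(pd.DataFrame(report.to_rows()), out / "filter_report.tsv", chash, seed)

        if opts["stages"]["diversity"]:
            stage = "diversity"
            het = het_stats(G, popmap)
            spec = RarefactionSpec(
                g=int(opts["diversity"]["g"]), tolerance=float(opts["diversity"]["tolerance"])
            )
            rich = rarefied_richness(G, popmap, spec)
            rows = [
                {
                    "group": g,
                    "n": het[g]["n"],
                    "H_O": het[g]["H_O"],
                    "H_E": het[g]["H_E"],
                    "A_R": rich[g]["A_R"],
                    "PA_R": rich[g]["PA_R"],
                    "N_PA": rich[g]["N_PA"],
                }
                for g in popmap.groups
            ]
            _write_tsv(pd.DataFrame(rows), out / "diversity.tsv", chash, seed)

            fst, _ = pairwise_fst(G, popmap)
            groups = popmap.groups
            # per-locus H_E vectors feed the rank-sum comparison
            he_vectors = {}
            for g in groups:
                calls = G.calls[[G.sample_index(s) for s in popmap.group_samples(g)], :]
                called = calls != MISSING
                nc = called.sum(axis=0)
                with np.errstate(invalid="ignore", divide="ignore"):
                    p = np.where(nc > 0, np.where(called, calls, 0).sum(axis=0) / (2 * np.maximum(nc, 1)), np.nan)
                he_vectors[g] = 2 * p * (1 - p)
            tests = {(t["group_a"], t["group_b"]): t for t in compare_groups(he_vectors)}
            fst_rows = []
            for i, ga in enumerate(groups):
                for gb in groups[i + 1 :]:
                    t = tests[(ga, gb)]
                    fst_rows.append(
                        {
                            "group_a": ga,
                            "group_b": gb,
                            "fst_wc84": fst[(ga, gb)],
                            "wilcoxon_p": t["p_raw"],
                            "p_bh": t["p_adj"],
                            "significant": t["significant"],
                        }
                    )
            _write_tsv(pd.DataFrame(fst_rows), out / "fst.tsv", chash, seed)

        if opts["stages"]["share"] and popmap.focal_samples:
            stage = "share"
            share_tol = float(opts["share"]["tolerance"])
            share_g = opts["share"]["g"]
            if share_g is None:
                share_g = max_feasible_g(popmap, share_tol)
            sspec = RarefactionSpec(g=int(share_g), tolerance=share_tol)
            share_rows, prop_rows, detail_rows = [], [], []
            for focal in popmap.focal_samples:
                rep = shared_private_report(
                    G,
                    popmap,
                    focal,
                    bin_width=float(opts["share"]["bin_width"]),
                    global_denominator=bool(opts["share"]["global_denominator"]),
                )
                spar = shared_private_richness(G, popmap, focal, sspec)
                for g in popmap.groups:
                    row = rep.table_row(g)
                    row["S_PAr"] = spar[g]
                    row["het_fraction"] = rep.per_group[g]["het_fraction"]
                    share_rows.append(row)
                    for b in rep.per_group[g]["propS_bins"]:
                        prop_rows.append({"focal": focal, "group": g, **b})
                    for d in rep.per_group[g]["shared_detail"]:
                        detail_rows.append({"focal": focal, "group": g, **d})
            _write_tsv(pd.DataFrame(share_rows), out / "sharing.tsv", chash, seed)
            _write_tsv(pd.DataFrame(prop_rows), out / "sharing_props.tsv", chash, seed)
            _write_tsv(pd.DataFrame(detail_rows), out / "sharing_detail.tsv", chash, seed)

            uniq = focal_unique_alleles(G, popmap)
            uniq_rows = [
                {
                    "focal": f,
                    "n_unique": len(c),
                    "hom_fraction": uniq["hom_fraction"][f],
                }
                for f, c in uniq["per_focal"].items()
            ]
            _write_tsv(pd.DataFrame(uniq_rows), out / "focal_unique.tsv", chash, seed)

            if len(popmap.focal_samples) >= 2:
                M, names = ibs_matrix(G, popmap.focal_samples)
                ibs_rows = [
                    {"sample_a": names[i], "sample_b": names[j], "ibs": M[i, j]}
                    for i in range(len(names))
                    for j in range(i + 1, len(names))
                ]
                _write_tsv(pd.DataFrame(ibs_rows), out / "ibs.tsv", chash, seed)

        if opts["stages"]["ancestry"] and popmap.focal_samples:
            stage = "ancestry"
            ref_a = opts["ancestry"]["ref_a"] or popmap.groups[0]
            ref_b = opts["ancestry"]["ref_b"] or popmap.groups[1]
            freq = allele_frequencies(G, popmap)
            fa = freq.freq[freq.row(ref_a)]
            fb = freq.freq[freq.row(ref_b)]
            anc_rows = []
            for focal in popmap.focal_samples:
                est = supervised_q(
                    G.calls[G.sample_index(focal), :],
                    fa,
                    fb,
                    epsilon=float(opts["ancestry"]["epsilon"]),
                    focal_name=focal,
                )
                anc_rows.append(
                    {
                        "focal": focal,
                        "ref_a": ref_a,
                        "ref_b": ref_b,
                        "q_a": est.q_a,
                        "q_b": est.q_b,
                        "log_likelihood": est.log_likelihood,
                        "n_loci": est.n_loci,
                        "identifiable": est.identifiable,
                    }
                )
            _write_tsv(pd.DataFrame(anc_rows), out / "ancestry.tsv", chash, seed)

        if opts["stages"]["pca"]:
            stage = "pca"
            pca = pca_projection(G)
            pca_rows = [
                {
                    "sample": s,
                    **{f"PC{c + 1}": pca.scores[i, c] for c in range(pca.scores.shape[1])},
                }
                for i, s in enumerate(pca.samples)
            ]
            _write_tsv(pd.DataFrame(pca_rows), out / "pca_scores.tsv", chash, seed)
            _write_tsv(
                pd.DataFrame(
                    {
                        "component": [f"PC{c + 1}" for c in range(len(pca.explained_variance_ratio))],
                        "explained_variance_ratio": pca.explained_variance_ratio,
                    }
                ),
                out / "pca_variance.tsv",
                chash,
                seed,
            )
    except Exception:
        logger.exception("pipeline aborted in stage %s (partial outputs in %s)", stage, out)
        raise

    provenance = {
        "version": __version__,
        "config_hash": chash,
        "seed": seed,
        "options": opts,
        "inputs": {
            "vcf": config.vcf,
            "popmap": config.popmap,
            "gene_models": config.gene_models,
            "simulate": config.simulate,
        },
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return out
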