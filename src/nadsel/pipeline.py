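"""Config-driven orchestration of the full selection-analysis pipeline.

A YAML/dict config lists stages (counts -> contrast -> sitesel -> scan ->
snpscreen) with per-stage parameters and mandatory seeds for every
stochastic step. Outputs are deterministic given config + inputs: result
tables are sorted, and a manifest records the config hash and seeds so
reruns are byte-comparable. A site-model fit failing for one gene is
logged and does not abort the remaining genes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import __version__
from . import codonmodels, contrasts, divcounts, popscan, seqio, snpscreen

logger = logging.getLogger(__name__)

KNOWN_STAGES = ("contrast", "sitesel", "scan", "snpscreen")


class ConfigError(ValueError):
    """Malformed pipeline configuration."""


def _require(cfg: dict, stage: str, *keys: str) -> None:
    for k in keys:
        if k not in cfg:
            raise ConfigError(f"stage {stage!r}: missing required key {k!r}")


def validate_config(config: dict) -> None:
    """Check the whole config before any stage runs."""
    if "stages" not in config or not config["stages"]:
        raise ConfigError("config must list at least one stage")
    for stage in config["stages"]:
        if stage not in KNOWN_STAGES:
            raise ConfigError(f"unknown stage {stage!r}; known: {KNOWN_STAGES}")
        sc = config.get(stage)
        if sc is None:
            raise ConfigError(f"stage {stage!r} listed but not configured")
        if stage == "contrast":
            _require(sc, stage, "counts", "seed")
        elif stage == "sitesel":
            _require(sc, stage, "genes", "tree", "alpha", "seed")
            if not 0 < sc["alpha"] < 1:
                raise ConfigError("sitesel: alpha must be in (0, 1)")
        elif stage == "scan":
            _require(sc, stage, "variants", "populations", "region", "statistic")
            if sc.get("subsamples") and "seed" not in sc:
                raise ConfigError("scan: subsampling requested without a seed")
        elif stage == "snpscreen":
            _require(sc, stage, "variants")
            if sc.get("downsample") and "seed" not in sc["downsample"]:
                raise ConfigError("snpscreen: downsampling requested without a seed")


def _config_hash(config: dict) -> str:
    canonical = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the configured stages in order; return the manifest dict."""
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "stages": {},
    }
    runners = {
        "contrast": _run_contrast,
        "sitesel": _run_sitesel,
        "scan": _run_scan,
        "snpscreen": _run_snpscreen,
    }
    for stage in config["stages"]:
        manifest["stages"][stage] = runners[stage](config[stage], outdir)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _run_contrast(cfg: dict, outdir: Path) -> dict:
    genes = divcounts.read_gene_counts(cfg["counts"])
    kinds = cfg.get("kinds", ["diversity", "divergence"])
    report = {"seed": cfg["seed"], "results": {}}
    for kind in kinds:
        gc = contrasts.permutation_contrast(
            genes,
            kind=kind,
            n_permutations=cfg.get("n_permutations", 9999),
            seed=cfg["seed"],
        )
        report["results"][kind] = {
            "biosynthetic_ratio": gc.group_a_ratio,
            "degrading_ratio": gc.group_b_ratio,
            "statistic": gc.statistic,
            "p_value": gc.p_value,
            "n_permutations": gc.n_permutations,
        }
    pn = sum(g.Pn for g in genes)
    ps = sum(g.Ps for g in genes)
    dn = sum(g.Dn for g in genes)
    ds = sum(g.Ds for g in genes)
    mk = contrasts.mk_test(pn, ps, dn, ds)
    report["mk_pooled"] = {
        "table": mk.table,
        "odds_ratio": mk.odds_ratio,
        "p_value": mk.p_value,
        "direction": mk.direction,
    }
    out = outdir / "contrast.json"
    with open(out, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return {"output": out.name}


def _run_sitesel(cfg: dict, outdir: Path) -> dict:
    tree = seqio.PhyloTree.from_newick(cfg["tree"])
    alpha = cfg["alpha"]
    genes = cfg["genes"]
    m = cfg.get("m_tests", len(genes))
    threshold = codonmodels.bonferroni_threshold(alpha, m)
    seed = cfg["seed"]
    n_restarts = cfg.get("n_restarts", 3)
    rows, failures = [], []
    for g in sorted(genes, key=lambda g: g["gene_id"]):
        gid = g["gene_id"]
        try:
            aln = seqio.read_codon_alignment(g["alignment"])
            aln, _ = seqio.mask_gapped_codon_columns(aln)
            fit1 = codonmodels.fit_model(
                aln, tree, "M1a", n_restarts=n_restarts, seed=seed
            )
            fit2 = codonmodels.fit_model(
                aln, tree, "M2a", n_restarts=n_restarts, seed=seed + 1
            )
            stat, p, df = codonmodels.site_model_lrt(fit1, fit2)
            row = {
                "gene_id": gid,
                "lnL_M1a": fit1.lnL,
                "lnL_M2a": fit2.lnL,
                "lrt_stat": stat,
                "p_value": p,
                "significant": p < threshold,
                "omega2": fit2.site_classes[-1][0],
                "p2": fit2.site_classes[-1][1],
            }
            ref = cfg.get("reference")
            if row["significant"] and ref and ref in aln.sequence_ids:
                sites = fit2.positive_sites(ref)
                row["positive_sites"] = [
                    s.reference_residue_position for s in sites
                ]
            rows.append(row)
        except Exception as exc:  # per-gene isolation
            logger.warning("site-model fit failed for %s: %s", gid, exc)
            failures.append({"gene_id": gid, "error": str(exc)})
    out = outdir / "sitesel.tsv"
    with open(out, "w") as fh:
        fh.write(
            "gene_id\tlnL_M1a\tlnL_M2a\tlrt_stat\tp_value\tsignificant\t"
            "omega2\tp2\tpositive_sites\n"
        )
        for r in rows:
            sites = ",".join(map(str, r.get("positive_sites", []))) or "."
            fh.write(
                f"{r['gene_id']}\t{r['lnL_M1a']:.4f}\t{r['lnL_M2a']:.4f}\t"
                f"{r['lrt_stat']:.4f}\t{r['p_value']:.3e}\t"
                f"{int(r['significant'])}\t{r['omega2']:.4f}\t{r['p2']:.4f}\t{sites}\n"
            )
    return {
        "output": out.name,
        "bonferroni_threshold": threshold,
        "significant_genes": sorted(r["gene_id"] for r in rows if r["significant"]),
        "failures": failures,
        "seed": seed,
    }


def _run_scan(cfg: dict, outdir: Path) -> dict:
    pops = list(cfg["populations"])
    variants, _ = seqio.read_variant_table(cfg["variants"], pops)
    region = tuple(cfg["region"])
    statistic = cfg["statistic"]
    default_window = 10_000 if statistic in ("fay_wu_H", "zeng_E") else 3_000
    windows = popscan.sliding_scan(
        variants,
        pops,
        region,
        window_bp=cfg.get("window", default_window),
        step_bp=cfg.get("step", 500),
        statistic=statistic,
        chrom=cfg.get("chrom", "."),
    )
    if cfg.get("subsamples"):
        windows = popscan.subsample_envelope(
            variants,
            pops,
            region,
            windows,
            pop_individuals=cfg["pop_individuals"],
            n_subsamples=cfg["subsamples"],
            subsample_size=cfg.get("subsample_size", 546),
            seed=cfg["seed"],
        )
    out = outdir / f"scan_{statistic}.tsv"
    popscan.write_window_stats(windows, out)
    return {"output": out.name, "n_windows": len(windows)}


def _run_snpscreen(cfg: dict, outdir: Path) -> dict:
    pops = list(cfg.get("populations", []))
    variants, _ = seqio.read_variant_table(cfg["variants"], pops)
    n_dropped = 0
    if cfg.get("downsample"):
        ds = cfg["downsample"]
        variants, n_dropped = snpscreen.binomial_downsample(
            variants,
            target_individuals=ds.get("target_individuals", 20),
            seed=ds["seed"],
        )
    changes = snpscreen.high_frequency_changes(
        variants, threshold=cfg.get("threshold", 0.20)
    )
    changes, n_rare = snpscreen.flag_rare_changes(changes)
    changes.sort(key=lambda c: (c.gene_id, c.protein_pos))
    out = outdir / "snpscreen.tsv"
    snpscreen.write_change_table(changes, out)
    return {
        "output": out.name,
        "n_changes": len(changes),
        "n_rare": n_rare,
        "n_dropped_monomorphic": n_dropped,
    }


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg
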