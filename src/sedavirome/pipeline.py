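"""Configuration-driven orchestration of the full analysis.

Stages run in a fixed order -- parse, aggregate, normalise, blanks,
damage, overlap/rarefaction, core similarity, virus-host -- each writing
its tables under the output directory with a comment header carrying the
config hash and seed, plus a JSON run manifest.  Validation happens
before any computation; a stage failure stops the run with the failing
stage named.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import (
    DEFAULT_DEPTHS,
    environment_overlap,
    rarefaction_overlap_curve,
    hellinger_transform,
)
from .coresim import CoreSeries, dissimilarity_matrix, pairwise_table
from .damage import (
    fit_damage_model,
    filter_ancient_contigs,
    position0_summary,
    read_damage_records,
    write_damage_fits,
)
from .tables import (
    DEFAULT_EPOCH_BOUNDARY,
    aggregate_cumulative,
    blank_summary,
    read_lca_counts,
    read_sample_metadata,
    relative_abundance,
    write_lca_counts,
)
from .taxonomy import parse_taxonomy
from .virushost import (
    build_host_groups,
    exclusion_sensitivity,
    group_abundance_series,
    positive_shift_test,
    read_pair_table,
    spearman,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = (
    "parse",
    "aggregate",
    "normalise",
    "blanks",
    "damage",
    "overlap",
    "coresim",
    "virushost",
)


class PipelineError(RuntimeError):
    """Configuration validation or stage failure (stage named in message)."""


@dataclass
class PipelineConfig:
    """Paths and analysis settings for one pipeline run."""

    outdir: str
    nodes: str
    names: str
    counts: str
    metadata: str
    pairs: str | None = None
    vmr: str | None = None
    damage: str | None = None
    seed: int = 0
    epoch_boundary: float = DEFAULT_EPOCH_BOUNDARY
    viral_root_name: str = "Viruses"
    rarefaction_depths: list = field(default_factory=lambda: list(DEFAULT_DEPTHS))
    rarefaction_reps: int = 3
    exclude_taxa: list = field(default_factory=list)  # names or taxids
    min_accuracy: float = 0.6
    min_length: int = 1000
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        required = {
            "nodes": self.nodes,
            "names": self.names,
            "counts": self.counts,
            "metadata": self.metadata,
        }
        optional = {"pairs": self.pairs, "vmr": self.vmr, "damage": self.damage}
        for key, p in {**required, **{k: v for k, v in optional.items() if v}}.items():
            if not Path(p).exists():
                raise PipelineError(f"validation: {key} path {p!r} does not exist")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, header: str, sep: str, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep=sep, index=index)


def run_pipeline(config: PipelineConfig, stages=None) -> dict:
    """Execute the requested stages; returns (and writes) the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    selected = list(stages) if stages else list(STAGES)
    bad = set(selected) - set(STAGES)
    if bad:
        raise PipelineError(f"validation: unknown stages {sorted(bad)}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"sedavirome {__version__} config_hash={config.config_hash()} seed={config.seed}"
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "stages": [],
        "files": {},
    }

    state: dict = {}

    def record(name: str, files: dict) -> None:
        manifest["stages"].append(name)
        manifest["files"].update({k: str(v) for k, v in files.items()})
        logger.info("stage %s complete", name)

    def run_stage(name: str, fn) -> None:
        if name not in selected and name not in ("parse", "aggregate", "normalise"):
            return
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # -- parse (always needed) ------------------------------------------
    def _parse():
        state["tree"] = parse_taxonomy(config.nodes, config.names)
        state["counts"], state["annotations"] = read_lca_counts(config.counts)
        state["meta"] = read_sample_metadata(config.metadata, config.epoch_boundary)
        record("parse", {})

    run_stage("parse", _parse)
    tree = state["tree"]
    meta = state["meta"]
    viral_root = tree.find_by_name(config.viral_root_name)
    exclude = set()
    for e in config.exclude_taxa:
        exclude.add(int(e) if str(e).isdigit() else tree.find_by_name(str(e)))

    def _aggregate():
        state["cum"] = aggregate_cumulative(state["counts"], tree)
        p = outdir / "cumulative_counts.tsv"
        ann = state["annotations"].reindex(state["cum"].data.index)
        ann["name"] = [tree.name(int(t)) for t in state["cum"].data.index]
        ann["rank"] = [tree.rank(int(t)) for t in state["cum"].data.index]
        write_lca_counts(state["cum"], ann, p, header_comment=header)
        record("aggregate", {"cumulative_counts": p})

    run_stage("aggregate", _aggregate)
    cum = state["cum"]

    def _normalise():
        state["ab_all"] = relative_abundance(cum, tree, "root")
        state["ab_viral"] = relative_abundance(cum, tree, viral_root)
        pa = outdir / "abundance_all_reads.tsv"
        pv = outdir / "abundance_viral_reads.tsv"
        _write_table(state["ab_all"].data, pa, header, "\t", True)
        _write_table(state["ab_viral"].data, pv, header, "\t", True)
        record("normalise", {"abundance_all_reads": pa, "abundance_viral_reads": pv})

    run_stage("normalise", _normalise)
    ab_all, ab_viral = state["ab_all"], state["ab_viral"]

    def _blanks():
        summ = blank_summary(cum, meta, viral_root)
        p = outdir / "blank_summary.json"
        with open(p, "w") as fh:
            json.dump(
                {
                    "n_blanks": summ.n_blanks,
                    "clean_blanks": summ.clean_blanks,
                    "blank_reads": summ.blank_reads,
                    "total_reads": summ.total_reads,
                    "fraction_pct": summ.fraction_pct,
                    "fraction_pct_2sf": summ.fraction_pct_rounded(2),
                },
                fh,
                indent=1,
            )
        record("blanks", {"blank_summary": p})

    run_stage("blanks", _blanks)

    def _damage():
        if not config.damage:
            return
        records = read_damage_records(config.damage)
        retained = filter_ancient_contigs(
            records, config.min_accuracy, config.min_length
        )
        fits = {r.contig_id: fit_damage_model(r.counts) for r in retained}
        pf = outdir / "damage_fits.tsv"
        write_damage_fits(retained, fits, pf, header_comment=header)
        summ = position0_summary(retained, tree, "superkingdom", fits=fits)
        ps = outdir / "damage_group_summary.tsv"
        _write_table(summ, ps, header, "\t", False)
        record("damage", {"damage_fits": pf, "damage_group_summary": ps})

    run_stage("damage", _damage)

    def _overlap():
        res = environment_overlap(cum, meta, tree, within=viral_root)
        po = outdir / "overlap.csv"
        df = pd.DataFrame(
            [
                {
                    "unique_lake": res.unique_a,
                    "unique_marine": res.unique_b,
                    "shared": res.shared,
                    "pct_unique_lake": res.pct_unique_a,
                    "pct_unique_marine": res.pct_unique_b,
                    "pct_shared": res.pct_shared,
                    "shared_read_fraction": res.shared_read_fraction,
                }
            ]
        )
        _write_table(df, po, header, ",", False)
        curve = rarefaction_overlap_curve(
            cum, meta, tree,
            depths=config.rarefaction_depths,
            reps=config.rarefaction_reps,
            seed=config.seed,
            within=viral_root,
        )
        pr = outdir / "rarefaction.csv"
        _write_table(curve.table, pr, header, ",", False)
        record("overlap", {"overlap": po, "rarefaction": pr})

    run_stage("overlap", _overlap)

    def _coresim():
        sites = sorted(
            meta.loc[meta["environment"] != "blank", "site"].unique()
        )
        cores = [CoreSeries.from_abundance(ab_viral, meta, s) for s in sites]
        mat = dissimilarity_matrix(cores, exclude_taxa=exclude)
        pm = outdir / "core_dissimilarity.tsv"
        _write_table(mat, pm, header, "\t", True)
        pt = outdir / "core_pairs.csv"
        _write_table(pairwise_table(cores, exclude_taxa=exclude), pt, header, ",", False)
        # Hellinger-transformed per-sample matrix for external ordination
        samples = meta.loc[meta["environment"] != "blank", "sample_id"]
        hmat = []
        kept = []
        for s in samples:
            v = ab_viral.data[s].fillna(0.0).to_numpy()
            if v.sum() > 0:
                hmat.append(hellinger_transform(v))
                kept.append(s)
        hdf = pd.DataFrame(
            np.column_stack(hmat), index=ab_viral.data.index, columns=kept
        )
        ph = outdir / "hellinger_viral.tsv"
        _write_table(hdf, ph, header, "\t", True)
        record(
            "coresim",
            {"core_dissimilarity": pm, "core_pairs": pt, "hellinger_viral": ph},
        )

    run_stage("coresim", _coresim)

    def _virushost():
        if not config.pairs:
            return
        pairs = read_pair_table(config.pairs)
        groups = build_host_groups(pairs, tree)
        sites = sorted(meta.loc[meta["environment"] != "blank", "site"].unique())
        rows = []
        for site in sites:
            for grp, taxa in sorted(groups.items()):
                for epoch in ("all", "Holocene", "Pleistocene"):
                    series = group_abundance_series(
                        ab_all, meta, site, grp, sorted(taxa)
                    )
                    sub = series.subset(epoch)
                    entry = {
                        "site": site,
                        "host_group": grp,
                        "host_group_name": tree.name(grp),
                        "epoch": epoch,
                        "n": len(sub),
                        "rho": float("nan"),
                        "pvalue": float("nan"),
                        "undefined": True,
                    }
                    if not series.empty and len(sub) >= 3:
                        try:
                            r = spearman(sub["virus"], sub["host"])
                            entry.update(
                                rho=r.rho, pvalue=r.pvalue, n=r.n,
                                undefined=r.undefined,
                            )
                        except Exception:  # degenerate subsets stay flagged
                            pass
                    rows.append(entry)
        corr = pd.DataFrame(rows)
        pc = outdir / "virushost_correlations.csv"
        _write_table(corr, pc, header, ",", False)

        shift_rows = []
        usable = corr[(corr["epoch"] == "all") & (~corr["undefined"])]
        envs = meta.loc[meta["environment"] != "blank", ["site", "environment"]]
        env_of = dict(zip(envs["site"], envs["environment"]))
        for env in ("lake", "marine", "both"):
            sel = usable if env == "both" else usable[
                usable["site"].map(env_of) == env
            ]
            rhos = sel["rho"].to_numpy()
            if len(rhos[rhos != 0]) == 0:
                continue
            t = positive_shift_test(rhos, "greater")
            shift_rows.append(
                {
                    "environment": env,
                    "n_coefficients": t.n,
                    "statistic": t.statistic,
                    "pvalue": t.pvalue,
                    "method": t.method,
                }
            )
        psh = outdir / "shift_tests.csv"
        _write_table(pd.DataFrame(shift_rows), psh, header, ",", False)
        record("virushost", {"virushost_correlations": pc, "shift_tests": psh})

    run_stage("virushost", _virushost)

    pman = outdir / "manifest.json"
    with open(pman, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
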