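"""End-to-end repertoire analysis: one configuration, one output bundle.

Stage order: abundance spectra -> alpha diversity -> beta diversity
(frequency filter, pooled tree, weighted UniFrac, PCoA, PERMANOVA on
endemic vs non-endemic region) -> gene usage (+ differential tests and
PCA) -> CDR3 features -> Hamming-distance networks. All stage outputs are
tab-separated tables under the output directory plus ``manifest.json``
(config echo, seed, version) and ``summary.json`` (headline numbers).
Identical (config, seed) produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .abundance import BINS, compare_bin_proportions, spectrum_table
from .airr_io import read_airr, write_airr
from .cdr3_features import chemistry, group_chemistry_comparison, length_table
from .diversity import alpha_diversity, beta_diversity, pcoa, permanova
from .gene_usage import active_disease_grouping, differential_usage, usage_frequencies, usage_pca
from .networks import build_network, component_report, extract_relevant
from .records import ENDEMIC_GROUPS, Cohort
from .synthetic import SyntheticConfig, simulate_cohort

ALL_STAGES = ("abundance", "diversity", "usage", "cdr3", "networks")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    airr_path: Optional[str] = None
    metadata_path: Optional[str] = None
    synthetic: Optional[SyntheticConfig] = None
    isotypes: Tuple[str, ...] = ("IGHM", "IGHG")
    #: beta-diversity frequency filter per isotype (strict >); None = keep all
    beta_min_frequency: Dict[str, Optional[float]] = field(
        default_factory=lambda: {"IGHG": 0.001, "IGHM": None}
    )
    permanova_permutations: int = 99999
    network_isotype: str = "IGHG"
    network_max_distance: int = 2
    network_min_samples: int = 4
    #: which samples count toward the relevance threshold
    network_restrict: str = "patients"  # "patients" | "endemic" | "all"
    stages: Tuple[str, ...] = ALL_STAGES
    seed: int = 0

    def validate(self) -> None:
        if (self.airr_path is None) == (self.synthetic is None):
            raise ValueError("configure exactly one of airr_path or synthetic")
        if self.airr_path is not None and self.metadata_path is None:
            raise ValueError("metadata_path required with airr_path")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.network_restrict not in ("patients", "endemic", "all"):
            raise ValueError(f"unknown network_restrict {self.network_restrict!r}")

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        if self.synthetic is not None:
            data["synthetic"] = _jsonable(dataclasses.asdict(self.synthetic))
        Path(path).write_text(yaml.safe_dump(_jsonable(data), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data.get("synthetic"):
            syn = data["synthetic"]
            if "v_usage_shifts" in syn:
                syn["v_usage_shifts"] = {
                    tuple(k.split(":", 1)): v for k, v in syn["v_usage_shifts"].items()
                }
            if "planted_clusters" in syn:
                from .synthetic import PlantedCluster

                syn["planted_clusters"] = tuple(
                    PlantedCluster(**{**c, "target_samples": tuple(c["target_samples"])})
                    for c in syn["planted_clusters"]
                )
            data["synthetic"] = SyntheticConfig(**syn)
        for key in ("isotypes", "stages"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {
            (f"{k[0]}:{k[1]}" if isinstance(k, tuple) else k): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _load_cohort(config: PipelineConfig) -> Cohort:
    if config.synthetic is not None:
        return simulate_cohort(config.synthetic)
    return read_airr(config.airr_path, config.metadata_path)


def _region_grouping(cohort: Cohort) -> Dict[str, str]:
    return {
        sid: ("endemic" if g in ENDEMIC_GROUPS else "nonendemic")
        for sid, g in cohort.metadata.items()
    }


def run_pipeline(config: PipelineConfig, out_dir) -> Dict:
    """Execute the configured stages; returns the summary dict."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: Dict = {"seed": config.seed, "stages": list(config.stages)}

    def _stage(name):
        def wrap(fn):
            if name not in config.stages:
                return
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - abort with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    cohort = _load_cohort(config)
    if config.synthetic is not None:
        write_airr(cohort, out / "cohort.tsv", out / "cohort_metadata.tsv")

    @_stage("abundance")
    def _run_abundance():
        spectrum_table(cohort).to_csv(out / "abundance_spectra.tsv", sep="\t", index=False)
        comps = []
        for isotype in config.isotypes:
            for b in BINS:
                comps.append(compare_bin_proportions(cohort, isotype, b))
        pd.concat(comps, ignore_index=True).to_csv(
            out / "abundance_comparisons.tsv", sep="\t", index=False
        )

    @_stage("diversity")
    def _run_diversity():
        alphas = []
        permanova_rows = []
        for isotype in config.isotypes:
            alphas.append(alpha_diversity(cohort, isotype))
            dm, tree = beta_diversity(
                cohort, isotype, min_frequency=config.beta_min_frequency.get(isotype)
            )
            dm.to_tsv(out / f"beta_unifrac_{isotype}.tsv")
            (out / f"beta_tree_{isotype}.nwk").write_text(tree.to_newick() + "\n")
            ord_res = pcoa(dm, n_axes=2)
            coords = pd.DataFrame(
                ord_res.coordinates,
                index=ord_res.labels,
                columns=[f"PCo{i + 1}" for i in range(ord_res.coordinates.shape[1])],
            )
            coords.index.name = "sample_id"
            with open(out / f"pcoa_{isotype}.tsv", "w") as fh:
                fh.write("# eigenvalues\t" + "\t".join(f"{v:.10g}" for v in ord_res.eigenvalues) + "\n")
                coords.to_csv(fh, sep="\t")
            grouping = {sid: g for sid, g in _region_grouping(cohort).items() if sid in dm.labels}
            res = permanova(dm, grouping, config.permanova_permutations, seed=config.seed)
            permanova_rows.append(
                {
                    "isotype": isotype,
                    "comparison": "endemic_vs_nonendemic",
                    "pseudo_F": res.pseudo_f,
                    "p_value": res.p_value,
                    "n_permutations": res.n_permutations,
                    "method": res.method,
                }
            )
            summary[f"permanova_p_{isotype}"] = res.p_value
        pd.concat(alphas, ignore_index=True).to_csv(
            out / "alpha_diversity.tsv", sep="\t", index=False
        )
        pd.DataFrame(permanova_rows).to_csv(out / "permanova.tsv", sep="\t", index=False)

    @_stage("usage")
    def _run_usage():
        for isotype in config.isotypes:
            for family in ("V", "J", "C"):
                table = usage_frequencies(cohort, family, isotype)
                table.frequencies.to_csv(
                    out / f"usage_{family}_{isotype}.tsv", sep="\t", index_label="sample_id"
                )
                if family != "V":
                    continue
                grouping = active_disease_grouping(table)
                diff = differential_usage(table, grouping)
                diff.to_csv(out / f"differential_usage_V_{isotype}.tsv", sep="\t", index=False)
                flagged = diff.loc[diff["flagged"], "segment"].tolist()
                summary[f"flagged_V_{isotype}"] = flagged
                if len(flagged) >= 2:
                    sub = table.frequencies.loc[sorted(grouping)]
                    sub_table = dataclasses.replace(
                        table, frequencies=sub, groups=table.groups.loc[sorted(grouping)]
                    )
                    pca_res = usage_pca(sub_table, flagged)
                    scores = pd.DataFrame(
                        pca_res.scores,
                        index=pca_res.labels,
                        columns=[f"PC{i + 1}" for i in range(pca_res.scores.shape[1])],
                    )
                    scores.index.name = "sample_id"
                    scores["status"] = [grouping[s] for s in pca_res.labels]
                    scores.to_csv(out / f"usage_pca_V_{isotype}.tsv", sep="\t")

    @_stage("cdr3")
    def _run_cdr3():
        length_table(cohort, dither_seed=config.seed).to_csv(
            out / "cdr3_lengths.tsv", sep="\t", index=False
        )
        ks_rows = []
        for isotype in config.isotypes:
            lengths_by_group: Dict[str, list] = {}
            for s in cohort.by_isotype(isotype):
                lengths_by_group.setdefault(s.group, []).extend(
                    s.df["cdr3_aa"].str.len().tolist()
                )
            for ga, gb in combinations(sorted(lengths_by_group), 2):
                res = stats.ks_2samp(lengths_by_group[ga], lengths_by_group[gb])
                ks_rows.append(
                    {
                        "isotype": isotype, "group_a": ga, "group_b": gb,
                        "ks_statistic": float(res.statistic), "p_value": float(res.pvalue),
                    }
                )
        pd.DataFrame(ks_rows).to_csv(out / "cdr3_length_comparisons.tsv", sep="\t", index=False)
        chem = pd.concat([chemistry(s) for s in cohort.samples], ignore_index=True)
        chem.to_csv(out / "cdr3_chemistry.tsv", sep="\t", index=False)
        comps = [group_chemistry_comparison(cohort, iso) for iso in config.isotypes]
        pd.concat(comps, ignore_index=True).to_csv(
            out / "cdr3_chemistry_comparisons.tsv", sep="\t", index=False
        )

    @_stage("networks")
    def _run_networks():
        restrict_nodes = (
            cohort.endemic_sample_ids if config.network_restrict != "all" else None
        )
        network = build_network(
            cohort,
            isotype=config.network_isotype,
            max_distance=config.network_max_distance,
            sample_ids=restrict_nodes,
        )
        restrict_count = {
            "patients": cohort.patient_sample_ids,
            "endemic": cohort.endemic_sample_ids,
            "all": None,
        }[config.network_restrict]
        relevant = extract_relevant(
            network, min_samples=config.network_min_samples, restrict_to=restrict_count
        )
        component_report(relevant).to_csv(out / "network_components.tsv", sep="\t", index=False)
        network.edge_table().to_csv(out / "network_edges.tsv", sep="\t", index=False)
        for i, comp in enumerate(relevant):
            comp.pfm.to_csv(out / f"network_pfm_{i}.tsv", sep="\t")
        summary["n_relevant_components"] = len(relevant)
        summary["n_patient_exclusive_components"] = sum(
            1 for c in relevant if c.exclusivity == "patient_exclusive"
        )

    manifest = {
        "package": "ighrep",
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "config": _jsonable(dataclasses.asdict(config)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    (out / "summary.json").write_text(json.dumps(_jsonable(summary), sort_keys=True, indent=2) + "\n")
    return summary
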