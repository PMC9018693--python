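"""End-to-end orchestration: simulate -> merge -> call -> tabulate -> stats.

A :class:`RunConfig` describes one full run: the amplicon geometries, the
tissue x stage x replicate design, per-sample read depth and error model,
the processing thresholds, rarefaction and ordination settings, and the
methylation-expression coupling for the simulated qPCR data. Every source
of randomness is derived from the single run seed through
``numpy.random.SeedSequence``, so a rerun with the same config is
bit-identical. Real FASTQ files can stand in for simulation on a per-sample
basis (see :class:`SampleSource`), which is how externally sequenced
amplicon data would slot into the same pipeline.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, reads, simulate, stats, tables
from .amplicon import AmpliconSpec
from .expression import expression_table
from .simulate import MixtureSpec, SampleMeta


@dataclass(frozen=True)
class AmpliconConfig:
    """Geometry of one simulated amplicon."""

    name: str
    n_cpgs: int
    length: int
    labels: tuple[int, ...]
    seed: int


#: the two demo amplicons: 7 CpGs in 388 bp and 8 CpGs in 403 bp, with
#: TSS-relative CpG labels spanning the promoter on either side of the TSS
DEMO_AMPLICONS = (
    AmpliconConfig("promoter_a", 7, 388, (-118, -91, -47, -3, 92, 112, 131), 11),
    AmpliconConfig(
        "promoter_b", 8, 403, (-227, -183, -137, -71, -51, 26, 85, 144), 12
    ),
)


@dataclass(frozen=True)
class SampleSource:
    """Where one sample's reads come from: simulation or FASTQ files."""

    meta: SampleMeta
    fastq_fw: str | None = None
    fastq_rv: str | None = None

    @property
    def simulated(self) -> bool:
        return self.fastq_fw is None


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    amplicons: tuple[AmpliconConfig, ...] = DEMO_AMPLICONS
    tissues: tuple[str, ...] = ("brain", "heart")
    stages: tuple[str, ...] = ("P1", "P15", "P60")
    replicates: int = 3
    n_reads_per_sample: int = 10_000
    conversion_rate: float = 0.995
    inappropriate_conversion_rate: float = 0.005
    seq_error_rate: float = 0.001
    min_overlap: int = 40
    max_mismatch_frac: float = 0.1
    min_read_conversion: float = 0.95
    min_identity: float = 0.8
    rarefaction_depth: int | None = None  # None -> min retained count
    ordination_metric: str = "braycurtis"
    ordination_method: str = "pcoa"
    expression_coupling: float = -0.9
    expression_noise_sd: float = 0.05
    spikein_reads: int = 5000
    seed: int = 0
    samples: tuple[SampleSource, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.samples:
            self.samples = tuple(
                SampleSource(
                    SampleMeta(
                        sample_id=f"{t}_{s}_r{r}", tissue=t, stage=s,
                        replicate=r,
                    )
                )
                for t in self.tissues
                for s in self.stages
                for r in range(1, self.replicates + 1)
            )
        if len({s.meta.sample_id for s in self.samples}) != len(self.samples):
            raise ValueError("sample_ids must be unique")
        if len(self.samples) == 0:
            raise ValueError("config must define at least one sample")

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "amplicons": [asdict(a) for a in self.amplicons],
            "tissues": list(self.tissues),
            "stages": list(self.stages),
            "replicates": self.replicates,
            "n_reads_per_sample": self.n_reads_per_sample,
            "conversion_rate": self.conversion_rate,
            "inappropriate_conversion_rate": self.inappropriate_conversion_rate,
            "seq_error_rate": self.seq_error_rate,
            "min_overlap": self.min_overlap,
            "max_mismatch_frac": self.max_mismatch_frac,
            "min_read_conversion": self.min_read_conversion,
            "min_identity": self.min_identity,
            "rarefaction_depth": self.rarefaction_depth,
            "ordination_metric": self.ordination_metric,
            "ordination_method": self.ordination_method,
            "expression_coupling": self.expression_coupling,
            "expression_noise_sd": self.expression_noise_sd,
            "spikein_reads": self.spikein_reads,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        amp = tuple(
            AmpliconConfig(
                name=a["name"], n_cpgs=a["n_cpgs"], length=a["length"],
                labels=tuple(a["labels"]), seed=a["seed"],
            )
            for a in doc.pop("amplicons", [asdict(a) for a in DEMO_AMPLICONS])
        )
        doc["tissues"] = tuple(doc.get("tissues", ("brain", "heart")))
        doc["stages"] = tuple(doc.get("stages", ("P1", "P15", "P60")))
        return cls(amplicons=amp, **doc)


@dataclass
class AmpliconResults:
    """All per-amplicon outputs of one run."""

    spec: AmpliconSpec
    filter_report: pd.DataFrame
    call_report: pd.DataFrame
    count_table: tables.EpialleleCountTable
    rarefied: tables.EpialleleCountTable
    class_dist: pd.DataFrame
    mean_meth: pd.Series
    per_cpg: pd.DataFrame
    ordination: tables.OrdinationResult
    expression: pd.DataFrame
    anova: pd.DataFrame
    pairwise: pd.DataFrame
    correlation: pd.DataFrame
    class_heatmap: stats.CorrelationHeatmap
    epiallele_heatmap: stats.CorrelationHeatmap
    ground_truth: dict[str, dict[str, int]]


@dataclass
class RunResult:
    config: RunConfig
    amplicons: dict[str, AmpliconResults]
    conversion: calling.ConversionEstimate
    manifest: dict


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage and sample."""


def _sample_reads(
    source: SampleSource,
    spec: AmpliconSpec,
    config: RunConfig,
    seed: int,
) -> tuple[list[str] | None, list[tuple[str, str]]]:
    """Ground-truth epialleles (None for file input) and read pairs."""
    if source.simulated:
        mix = simulate.tissue_stage_mixture(
            k=spec.n_cpgs,
            tissue=source.meta.tissue,
            stage=source.meta.stage,
            n_molecules=config.n_reads_per_sample,
            seed=seed,
            conversion_rate=config.conversion_rate,
            inappropriate_conversion_rate=config.inappropriate_conversion_rate,
            seq_error_rate=config.seq_error_rate,
        )
        return simulate.simulate_sample_reads(spec, mix)
    pairs = [
        (str(a.seq), str(b.seq))
        for a, b in reads.read_fastq_pairs(source.fastq_fw, source.fastq_rv)
    ]
    return None, pairs


def run_pipeline(
    config: RunConfig, outdir: str | Path | None = None
) -> RunResult:
    """Execute the full pipeline; optionally write all tables under outdir."""
    seed_root = np.random.SeedSequence(config.seed)
    n_amp = len(config.amplicons)
    amp_seeds = seed_root.spawn(n_amp + 1)
    results: dict[str, AmpliconResults] = {}

    for ai, amp_cfg in enumerate(config.amplicons):
        spec = simulate.make_amplicon_spec(
            n_cpgs=amp_cfg.n_cpgs,
            length=amp_cfg.length,
            labels=list(amp_cfg.labels),
            seed=amp_cfg.seed,
            name=amp_cfg.name,
        )
        # one derived stream per sample, plus one each for rarefaction
        # and expression noise
        sample_seeds = amp_seeds[ai].generate_state(
            len(config.samples) + 2
        ) % (2 ** 31)
        calls_by_sample: dict[str, list[calling.ReadCall]] = {}
        truth: dict[str, dict[str, int]] = {}
        filter_rows = []
        call_rows = []
        for si, source in enumerate(config.samples):
            sid = source.meta.sample_id
            try:
                molecules, pairs = _sample_reads(
                    source, spec, config, int(sample_seeds[si])
                )
                merged, n_unmerged = reads.merge_read_pairs(
                    pairs,
                    min_overlap=config.min_overlap,
                    max_mismatch_frac=config.max_mismatch_frac,
                    sample_id=sid,
                )
                kept, freport = reads.filter_reads(merged, spec)
                calls = calling.call_reads(
                    kept, spec, sample_id=sid,
                    min_identity=config.min_identity,
                )
                retained, creport = calling.filter_by_conversion(
                    calls, min_read_conversion=config.min_read_conversion
                )
            except Exception as exc:  # noqa: BLE001 - label the stage
                raise PipelineError(
                    f"amplicon {spec.name!r}, sample {sid!r}: {exc}"
                ) from exc
            calls_by_sample[sid] = retained
            if molecules is not None:
                t: dict[str, int] = {}
                for m in molecules:
                    t[m] = t.get(m, 0) + 1
                truth[sid] = t
            filter_rows.append(
                {
                    "sample_id": sid,
                    "n_pairs": len(pairs),
                    "n_merged": len(merged),
                    "n_unmerged": n_unmerged,
                    **{f"filter_{k}": v for k, v in sorted(freport.items())},
                }
            )
            call_rows.append(
                {
                    "sample_id": sid,
                    "n_called": creport["retained"],
                    "n_low_conversion": creport["low_conversion"],
                    "n_uncalled": creport["uncalled"],
                    "bisulfite_efficiency": (
                        float(np.mean([c.read_conversion for c in calls]))
                        if calls else float("nan")
                    ),
                }
            )

        table = tables.build_count_table(
            calls_by_sample, spec, meta=[s.meta for s in config.samples]
        )
        depth = config.rarefaction_depth or int(table.row_sums().min())
        rarefied = tables.rarefy(
            table, depth=depth, seed=int(sample_seeds[-2])
        )
        class_dist = tables.class_distribution(rarefied)
        mean_meth = tables.mean_methylation(table)
        per_cpg = tables.per_cpg_methylation(table, spec)
        ordination = tables.ordinate(
            rarefied,
            metric=config.ordination_metric,
            method=config.ordination_method,
        )

        expr_seed = int(sample_seeds[-1])
        records = simulate.simulate_expression(
            mean_methylation=dict(mean_meth),
            coupling=config.expression_coupling,
            noise_sd=config.expression_noise_sd,
            seed=expr_seed,
            transcript=spec.name,
        )
        expr = expression_table(records)

        meta = table.meta
        anova_rows, pair_rows, corr_rows = [], [], []
        for tissue in sorted(meta["tissue"].dropna().unique()):
            ids = meta.index[meta["tissue"] == tissue]
            groups = {
                stage: list(mean_meth.loc[
                    ids.intersection(meta.index[meta["stage"] == stage])
                ])
                for stage in config.stages
            }
            groups = {g: v for g, v in groups.items() if len(v) >= 2}
            if len(groups) >= 2:
                a = stats.anova_oneway(groups)
                anova_rows.append(
                    {"tissue": tissue, "F": a.statistic, "p": a.p_value,
                     "n": a.n}
                )
                for t in stats.pairwise_t_tests(groups):
                    pair_rows.append(
                        {"tissue": tissue, "pair": "-".join(t.groups),
                         "t": t.statistic, "p": t.p_value, "n": t.n}
                    )
            c = stats.methylation_expression_correlation(
                mean_meth.loc[ids], expr.loc[ids, "rel_expr"]
            )
            corr_rows.append(
                {"tissue": tissue, "r": c.statistic, "p": c.p_value, "n": c.n}
            )

        class_hm = stats.class_expression_heatmap(
            rarefied, expr["rel_expr"], tissues=meta["tissue"]
        )
        epi_hm = stats.epiallele_expression_heatmap(
            rarefied, expr["rel_expr"], tissues=meta["tissue"]
        )

        results[spec.name] = AmpliconResults(
            spec=spec,
            filter_report=pd.DataFrame(filter_rows).set_index("sample_id"),
            call_report=pd.DataFrame(call_rows).set_index("sample_id"),
            count_table=table,
            rarefied=rarefied,
            class_dist=class_dist,
            mean_meth=mean_meth,
            per_cpg=per_cpg,
            ordination=ordination,
            expression=expr,
            anova=pd.DataFrame(anova_rows),
            pairwise=pd.DataFrame(pair_rows),
            correlation=pd.DataFrame(corr_rows),
            class_heatmap=class_hm,
            epiallele_heatmap=epi_hm,
            ground_truth=truth,
        )

    spike_seed = int(amp_seeds[-1].generate_state(1)[0] % (2 ** 31))
    spike_reads, spike_ref = simulate.simulate_spikein(
        n_reads=config.spikein_reads,
        conversion_rate=config.conversion_rate,
        seed=spike_seed,
    )
    conversion = calling.estimate_conversion_efficiency(spike_reads, spike_ref)

    manifest = {
        "seed": config.seed,
        "n_samples": len(config.samples),
        "n_reads_per_sample": config.n_reads_per_sample,
        "thresholds": {
            "min_overlap": config.min_overlap,
            "max_mismatch_frac": config.max_mismatch_frac,
            "min_read_conversion": config.min_read_conversion,
            "min_identity": config.min_identity,
        },
        "rarefaction_depth": {
            name: int(r.rarefied.rarefied_depth) for name, r in results.items()
        },
        "ordination": {
            "metric": config.ordination_metric,
            "method": config.ordination_method,
        },
        "conversion_efficiency": {
            "estimate": conversion.efficiency,
            "ci_low": conversion.ci_low,
            "ci_high": conversion.ci_high,
            "n_sites": conversion.n_sites,
        },
    }
    run = RunResult(
        config=config, amplicons=results, conversion=conversion,
        manifest=manifest,
    )
    if outdir is not None:
        write_outputs(run, outdir)
    return run


def write_outputs(run: RunResult, outdir: str | Path) -> None:
    """Write every table of a run as TSV/JSON under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, res in run.amplicons.items():
        d = out / name
        d.mkdir(exist_ok=True)
        (d / "amplicon.json").write_text(
            json.dumps(res.spec.to_dict(), sort_keys=True)
        )
        res.filter_report.to_csv(d / "filter_report.tsv", sep="\t")
        res.call_report.to_csv(d / "call_report.tsv", sep="\t")
        res.count_table.to_tsv(d / "epiallele_counts.tsv")
        res.count_table.to_biom_json(d / "epiallele_counts.biom.json",
                                     table_id=name)
        res.rarefied.to_tsv(d / "epiallele_counts_rarefied.tsv")
        res.class_dist.to_csv(d / "class_distribution.tsv", sep="\t")
        res.mean_meth.to_csv(d / "mean_methylation.tsv", sep="\t")
        res.per_cpg.to_csv(d / "per_cpg_methylation.tsv", sep="\t")
        res.ordination.coordinates.to_csv(d / "ordination.tsv", sep="\t")
        res.expression.to_csv(d / "expression.tsv", sep="\t")
        res.anova.to_csv(d / "anova.tsv", sep="\t", index=False)
        res.pairwise.to_csv(d / "pairwise_t.tsv", sep="\t", index=False)
        res.correlation.to_csv(d / "methylation_expression_correlation.tsv",
                               sep="\t", index=False)
        res.class_heatmap.r.to_csv(d / "class_expression_r.tsv", sep="\t")
        res.epiallele_heatmap.r.to_csv(d / "epiallele_expression_r.tsv",
                                       sep="\t")
        if res.ground_truth:
            with open(d / "ground_truth.tsv", "w") as fh:
                fh.write("sample_id\tepiallele\tcount\n")
                for sid in sorted(res.ground_truth):
                    for allele in sorted(res.ground_truth[sid]):
                        fh.write(
                            f"{sid}\t{allele}\t{res.ground_truth[sid][allele]}\n"
                        )
    (out / "manifest.json").write_text(
        json.dumps(run.manifest, sort_keys=True, indent=1)
    )
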