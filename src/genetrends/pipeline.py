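"""End-to-end orchestration: corpus -> annotations -> countries -> metrics
-> itemsets -> network -> clustering, with a reproducible run manifest.

The manifest records the configuration, the seed, per-stage record counts
(the corpus funnel: retrieved -> complete -> gene-bearing) and every file
written. It deliberately contains no timestamps so that two runs with the
same config and seed produce byte-identical manifests; stage timings go to
the log only.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clustering import (
    crossmatch_itemsets,
    fcm,
    fuzzy_area_genes,
    hierarchical_complete,
    validity_scan,
)
from .cooccurrence_network import (
    analyze,
    build_network,
    giant_component,
    prune,
    summarize,
    write_edgelist,
)
from .corpus_io import filter_complete, read_jsonl, read_medline_xml, write_jsonl
from .gene_annotation import (
    annotate_corpus,
    filter_gene_bearing,
    read_lexicon_tsv,
    write_annotated_jsonl,
)
from .geo_resolver import CountryGazetteer, ResolutionCache, resolve_corpus
from .pattern_mining import (
    build_country_transactions,
    build_year_transactions,
    itemsets_to_frame,
    mine_closed,
)
from .trend_metrics import (
    UNRESOLVED,
    collaborations,
    effort,
    gene_country_counts,
    top_k,
)

log = logging.getLogger("genetrends.pipeline")

#: fixed per-stage seed offsets, fanned out from the single run seed
STAGE_SEED_OFFSETS = {"network": 601, "clustering": 701}


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths, thresholds and the seed for one pipeline run."""

    corpus: str
    lexicon: str
    gazetteer: str
    outdir: str
    min_weight: int = 10
    min_support_pct: float = 40.0
    tau: float = 0.6
    c_min: int = 2
    c_max: int = 6
    fcm_c: int = 3
    m: float = 2.0
    metric: str = "cosine"
    resolution: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("corpus", "lexicon", "gazetteer"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


def _stage(manifest: dict, name: str, started: float, **info) -> None:
    log.info("stage %-12s done in %.2fs", name, time.perf_counter() - started)
    manifest["stages"].append({"name": name, **info})


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "seed": config.seed,
        "package_version": __version__,
        "stages": [],
    }

    stage = "corpus_filter"
    try:
        t0 = time.perf_counter()
        corpus_path = Path(config.corpus)
        if corpus_path.suffix.lower() == ".xml":
            corpus = read_medline_xml(corpus_path)
        else:
            corpus = read_jsonl(corpus_path)
        retrieved = len(corpus)
        corpus, report = filter_complete(corpus)
        write_jsonl(corpus, outdir / "corpus_filtered.jsonl")
        _stage(manifest, stage, t0, retrieved=retrieved, complete=len(corpus),
               removed=report, outputs=["corpus_filtered.jsonl"])

        stage = "annotate"
        t0 = time.perf_counter()
        lexicon, ambiguous = read_lexicon_tsv(config.lexicon)
        annotated = filter_gene_bearing(annotate_corpus(corpus, lexicon))
        _stage(manifest, stage, t0, gene_bearing=len(annotated),
               ambiguous_synonyms=len(ambiguous), outputs=[])

        stage = "geo_resolve"
        t0 = time.perf_counter()
        gazetteer = CountryGazetteer.from_tsv(config.gazetteer)
        cache = ResolutionCache()
        resolve_corpus(annotated, gazetteer, cache)
        cache.to_tsv(outdir / "geo_cache.tsv")
        write_annotated_jsonl(annotated, outdir / "annotated.jsonl")
        n_unresolved = sum(1 for a in annotated if not a.countries)
        _stage(manifest, stage, t0, cache_hits=cache.hits, cache_misses=cache.misses,
               unresolved_records=n_unresolved,
               outputs=["annotated.jsonl", "geo_cache.tsv"])

        stage = "metrics"
        t0 = time.perf_counter()
        counts = gene_country_counts(annotated)
        counts.to_tidy().to_csv(outdir / "gene_country_counts.csv", index=False)
        eff = effort(counts)
        eff.stack().rename("effort").reset_index().to_csv(
            outdir / "effort.csv", index=False
        )
        collaborations(annotated).to_tidy().to_csv(
            outdir / "collaborations.csv", index=False
        )
        n_rankable = (counts.row_margin.drop(index=UNRESOLVED, errors="ignore") > 0).sum()
        top_countries = top_k(counts, "country", min(10, int(n_rankable)))
        top_genes = top_k(counts, "gene", min(10, counts.matrix.shape[1]))
        _stage(manifest, stage, t0,
               top_countries=[list(t) for t in top_countries],
               top_genes=[list(t) for t in top_genes],
               outputs=["gene_country_counts.csv", "effort.csv",
                        "collaborations.csv"])

        stage = "pattern_mining"
        t0 = time.perf_counter()
        country_db = build_country_transactions(annotated)
        year_db, skipped = build_year_transactions(annotated)
        country_db.to_basket(outdir / "transactions_country.basket")
        year_db.to_basket(outdir / "transactions_year.basket")
        country_sets = mine_closed(country_db, config.min_support_pct)
        year_sets = mine_closed(year_db, config.min_support_pct)
        itemsets_to_frame(country_sets).to_csv(
            outdir / "itemsets_country.csv", index=False
        )
        itemsets_to_frame(year_sets).to_csv(outdir / "itemsets_year.csv", index=False)
        _stage(manifest, stage, t0,
               country_transactions=country_db.n, year_transactions=year_db.n,
               yearless_skipped=skipped,
               closed_country=len(country_sets), closed_year=len(year_sets),
               outputs=["transactions_country.basket", "transactions_year.basket",
                        "itemsets_country.csv", "itemsets_year.csv"])

        stage = "network"
        t0 = time.perf_counter()
        full = build_network(annotated)
        giant = giant_component(full)
        pruned = prune(giant, config.min_weight)
        summary = summarize(full, giant, pruned)
        summary.to_csv(outdir / "network_summary.csv", index=False)
        write_edgelist(pruned, outdir / "network_pruned_edges.tsv")
        result = analyze(
            pruned,
            seed=config.seed + STAGE_SEED_OFFSETS["network"],
            resolution=config.resolution,
        )
        result.to_frame().to_csv(outdir / "network_nodes.csv", index=False)
        _stage(manifest, stage, t0,
               summary=summary.to_dict(orient="records"),
               modularity=result.modularity,
               n_communities=len(set(result.modularity_class.values())),
               outputs=["network_summary.csv", "network_pruned_edges.tsv",
                        "network_nodes.csv"])

        stage = "clustering"
        t0 = time.perf_counter()
        matrix = counts.matrix.drop(index=UNRESOLVED, errors="ignore")
        matrix = matrix.loc[matrix.sum(axis=1) > 0]
        outputs = []
        if matrix.shape[0] >= 2:
            dendro = hierarchical_complete(matrix, metric=config.metric)
            (outdir / "country_dendrogram.nwk").write_text(
                dendro.to_newick() + "\n", encoding="utf-8"
            )
            dendro.to_frame().to_csv(outdir / "country_dendrogram.csv", index=False)
            outputs += ["country_dendrogram.nwk", "country_dendrogram.csv"]
        gene_features = matrix.T  # genes x countries
        seed_fcm = config.seed + STAGE_SEED_OFFSETS["clustering"]
        indices = None
        if gene_features.shape[0] >= max(config.c_min, 2):
            indices, _ = validity_scan(
                gene_features, c_min=config.c_min,
                c_max=min(config.c_max, gene_features.shape[0]),
                m=config.m, seed=seed_fcm,
            )
            indices.to_csv(outdir / "validity_indices.csv")
            outputs.append("validity_indices.csv")
        fuzzy = set()
        if gene_features.shape[0] >= config.fcm_c:
            chosen = fcm(gene_features, c=config.fcm_c, m=config.m, seed=seed_fcm)
            pd.DataFrame(
                chosen.membership.T,
                index=gene_features.index,
                columns=[f"cluster_{i}" for i in range(config.fcm_c)],
            ).to_csv(outdir / "fcm_membership.csv")
            fuzzy = fuzzy_area_genes(
                chosen.membership, list(gene_features.index), tau=config.tau
            )
            maximal_country = [it for it in country_sets if it.maximal]
            crossmatch_itemsets(
                maximal_country[:5], fuzzy, universe=set(gene_features.index)
            ).to_csv(outdir / "itemset_fuzzy_crossmatch.csv", index=False)
            outputs += ["fcm_membership.csv", "itemset_fuzzy_crossmatch.csv"]
        _stage(manifest, stage, t0,
               n_fuzzy_area=len(fuzzy),
               validity_cs=list(map(int, indices.index)) if indices is not None else [],
               outputs=outputs)
    except Exception as exc:  # noqa: BLE001 - rewrap with the failing stage name
        raise PipelineError(stage, exc) from exc

    manifest["funnel"] = {
        "retrieved": manifest["stages"][0]["retrieved"],
        "complete": manifest["stages"][0]["complete"],
        "gene_bearing": manifest["stages"][1]["gene_bearing"],
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
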