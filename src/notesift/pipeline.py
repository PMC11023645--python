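"""End-to-end study replica on synthetic data with the mock backend.

``run_study`` executes the staged workflow: simulate a keyword-filtered
development corpus and an unfiltered test corpus, screen, train the two
local classifiers, compare prompting strategies on the development holdout
(selection criterion: accuracy), run the winning strategy plus both
classifiers on the test corpus, ensemble by majority vote, and emit
interpretation keyword reports and the error-profile Venn decomposition.
Every artifact lands under one run directory together with a manifest
(config, per-stage seeds, file checksums, metric tables).

One master seed fans out deterministically to per-stage seeds through
``numpy.random.SeedSequence`` spawned in a fixed, documented order
(:data:`STAGE_ORDER`), so any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, interpretation
from .baselines import GbtClassifier, scores_to_csv, scores_to_table
from .corpus import Corpus
from .nn import AttentionDnnClassifier
from .prompting import (
    BackendConfig,
    MockBackend,
    PromptTemplate,
    build_error_instructions,
    default_template,
    effective_rate,
    entries_to_replies,
    replies_to_jsonl,
    run_prompting,
)
from .screen import expert_patterns, load_keywords, screen_sections
from .simulate import filtered_spec, generate_corpus, split_corpus, unfiltered_spec

log = logging.getLogger("notesift.pipeline")

# Mock-backend error rates per prompting strategy: the study conditions the
# pipeline emulates (development-set accuracy ~= 1 - rate). Error-analysis
# instructions help most; five-shot augmentation does not beat zero-shot.
DEFAULT_STRATEGY_ERROR_RATES: dict[str, float] = {
    "zero_shot": 0.135,
    "random": 0.17,
    "targeted": 0.16,
    "kmeans": 0.16,
    "dynamic": 0.15,
    "error_instructions": 0.07,
}

# Fixed fan-out order of per-stage seeds derived from the master seed.
STAGE_ORDER = (
    "corpus_filtered",
    "corpus_unfiltered",
    "split",
    "gbt",
    "dnn",
    "strategy_pool_probe",
    "strategy_zero_shot",
    "strategy_random",
    "strategy_targeted",
    "strategy_kmeans",
    "strategy_dynamic",
    "strategy_error_instructions",
    "final_llm",
)


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Derive one sub-2^31 integer seed per pipeline stage."""
    children = np.random.SeedSequence(master_seed).spawn(len(STAGE_ORDER))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(STAGE_ORDER, children)
    }


@dataclass
class RunConfig:
    """Everything a full study replica needs; the master seed plus this
    config fully determine every stochastic stage."""

    seed: int = 0
    out_dir: str = "run"
    filtered_n: int = 4949
    filtered_prevalence: float = 0.294
    split_sizes: tuple[int, int] = (4749, 200)
    unfiltered_n: int = 1996
    unfiltered_prevalence: float = 0.035
    gbt_params: dict = field(default_factory=dict)
    dnn_params: dict = field(default_factory=dict)
    strategies: tuple[str, ...] = tuple(DEFAULT_STRATEGY_ERROR_RATES)
    strategy_error_rates: dict = field(
        default_factory=lambda: dict(DEFAULT_STRATEGY_ERROR_RATES)
    )
    n_shots: int = 5
    abstention_policy: str = "negative"  # or "defer"
    temperature: float = 0.0

    def __post_init__(self) -> None:
        if self.abstention_policy not in ("negative", "defer"):
            raise ValueError("abstention_policy must be 'negative' or 'defer'")
        if self.temperature != 0.0:
            raise ValueError("study-replication runs require temperature 0")
        unknown = set(self.strategies) - set(self.strategy_error_rates)
        if unknown:
            raise ValueError(f"strategies without an error rate: {sorted(unknown)}")
        if sum(self.split_sizes) > self.filtered_n:
            raise ValueError("split sizes exceed the filtered corpus size")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "split_sizes" in doc:
            doc["split_sizes"] = tuple(doc["split_sizes"])
        if "strategies" in doc:
            doc["strategies"] = tuple(doc["strategies"])
        return cls(**doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["split_sizes"] = list(self.split_sizes)
        d["strategies"] = list(self.strategies)
        return d


def small_config(out_dir: str, seed: int = 0) -> RunConfig:
    """Desk-scale configuration: same structure, reduced sizes.

    The attention network is sized down (16-dim everywhere, word dropout
    0.2, weight decay 1e-3) to match the reduced corpus; the full-size
    default network overfits scaffold sentences at this scale.
    """
    return RunConfig(
        seed=seed,
        out_dir=out_dir,
        filtered_n=1200,
        split_sizes=(1000, 200),
        unfiltered_n=600,
        dnn_params=dict(
            embed_dim=16, n_filters=16, hidden_size=16, attn_size=16,
            max_len=128, epochs=10, batch_size=32,
            word_dropout=0.2, weight_decay=1e-3,
        ),
        gbt_params=dict(n_estimators=150),
    )


def llm_label_table(
    entries: list[dict],
    policy: str = "negative",
    dnn_table: dict[str, int] | None = None,
    gbt_table: dict[str, int] | None = None,
) -> dict[str, int]:
    """Per-section LLM labels with the abstention policy applied.

    ``negative``: an abstention (not-effective reply) votes 0. ``defer``:
    the two local models decide, the boosted-tree model breaking ties.
    """
    out = {}
    for e in entries:
        verdict = e["verdict"]
        if verdict is None:
            if policy == "negative":
                verdict = 0
            else:
                if dnn_table is None or gbt_table is None:
                    raise ValueError("defer policy needs both local model tables")
                sid = e["section_id"]
                verdict = gbt_table[sid] if dnn_table[sid] != gbt_table[sid] else dnn_table[sid]
        out[e["section_id"]] = int(verdict)
    return out


def categorize_error(section, predicted: int) -> str:
    """Heuristic error-category tag for one misclassified synthetic section,
    read off the generation metadata."""
    kind = section.meta.get("kind", "")
    if section.label == 1 and predicted == 0:
        return "over-conservative"
    if kind == "negated":
        return "misread-negation"
    if kind == "transient":
        return "transient-cause"
    if kind == "benign_keyword":
        return "overinterpretation"
    return "unrelated-condition"


def _error_instruction_template(
    config: RunConfig, dev: Corpus, seeds: dict[str, int], template: PromptTemplate
) -> PromptTemplate:
    """Template carrying the error-analysis paragraph built from a seeded
    zero-shot probe of the development corpus (deterministic given seeds)."""
    dev_probe = llm_label_table(
        run_prompting(
            MockBackend(
                BackendConfig(
                    seed=seeds["strategy_zero_shot"],
                    mock_error_rate=config.strategy_error_rates.get("zero_shot", 0.1),
                )
            ),
            template,
            dev,
            strategy="none",
        ),
        "negative",
    )
    categorized = [
        (sid, categorize_error(dev.by_id(sid), lab))
        for sid, lab in dev_probe.items()
        if lab != dev.by_id(sid).label
    ]
    return PromptTemplate(
        template.task_description,
        template.task_guidance,
        [],
        build_error_instructions(categorized) or None,
        name="error_instructions",
    )


def compare_strategies(
    config: RunConfig,
    dev: Corpus,
    pool: Corpus,
    seeds: dict[str, int],
    out_dir: Path | None = None,
    strategies: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[dict]]]:
    """One row per prompting strategy: development-set accuracy and
    effective-rate columns. Returns the table and the per-strategy reply
    logs so accuracies can be recomputed from persisted artifacts."""
    strategies = strategies if strategies is not None else config.strategies
    if len(strategies) < 1:
        raise ValueError("at least one strategy is required")
    template = default_template()
    gold = dict(zip(dev.ids, dev.labels))
    rows = []
    logs: dict[str, list[dict]] = {}

    # probe run over the pool: prior errors for the targeted strategy, and
    # categorized development errors for the instruction paragraph
    probe_cfg = BackendConfig(
        seed=seeds["strategy_pool_probe"],
        mock_error_rate=config.strategy_error_rates.get("zero_shot", 0.1),
    )
    probe_entries = run_prompting(MockBackend(probe_cfg), template, pool, strategy="none")
    probe_table = llm_label_table(probe_entries, "negative")
    prior_error_ids = {
        sid for sid, lab in probe_table.items() if lab != pool.by_id(sid).label
    }

    for strat in strategies:
        rate = config.strategy_error_rates[strat]
        seed = seeds[f"strategy_{strat}"]
        backend = MockBackend(BackendConfig(seed=seed, mock_error_rate=rate))
        tpl = template
        run_strategy = strat
        if strat == "zero_shot":
            run_strategy = "none"
        elif strat == "error_instructions":
            run_strategy = "none"
            tpl = _error_instruction_template(config, dev, seeds, template)
        try:
            entries = run_prompting(
                backend,
                tpl,
                dev,
                strategy=run_strategy,
                pool=pool if run_strategy != "none" else None,
                k=config.n_shots,
                seed=seed,
                prior_error_ids=prior_error_ids,
            )
        except ValueError as exc:  # e.g. too few prior errors for 'targeted'
            log.warning("strategy %s skipped: %s", strat, exc)
            rows.append(
                {"strategy": strat, "n": len(dev), "accuracy": np.nan,
                 "effective_rate": np.nan, "parseable_rate": np.nan,
                 "mock_error_rate": rate, "skipped": str(exc)}
            )
            continue
        table = llm_label_table(entries, "negative")
        acc = float(np.mean([table[sid] == gold[sid] for sid in gold]))
        replies = entries_to_replies(entries)
        rows.append(
            {
                "strategy": strat,
                "n": len(dev),
                "accuracy": acc,
                "effective_rate": effective_rate(replies),
                "parseable_rate": effective_rate(replies, include_unparseable=False),
                "mock_error_rate": rate,
                "skipped": "",
            }
        )
        logs[strat] = entries
        if out_dir is not None:
            replies_to_jsonl(entries, out_dir / f"replies_dev_{strat}.jsonl")
    table = pd.DataFrame(rows)
    return table, logs


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(config: RunConfig) -> dict:
    """Execute the full staged workflow; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "stages": {},
    }

    def stage(name):
        t0 = time.perf_counter()
        log.info("stage %s: start", name)

        def done(**extra):
            manifest["stages"][name] = {
                "wall_time_s": round(time.perf_counter() - t0, 3), **extra
            }
            log.info("stage %s: done", name)

        return done

    try:
        # -- simulate ----------------------------------------------------
        done = stage("simulate")
        filtered = generate_corpus(
            filtered_spec(config.filtered_n, config.filtered_prevalence,
                          seeds["corpus_filtered"])
        )
        unfiltered = generate_corpus(
            unfiltered_spec(config.unfiltered_n, config.unfiltered_prevalence,
                            seeds["corpus_unfiltered"])
        )
        filtered.to_jsonl(out / "corpus_filtered.jsonl")
        unfiltered.to_jsonl(out / "corpus_unfiltered.jsonl")
        done(filtered_n=len(filtered), unfiltered_n=len(unfiltered),
             filtered_prevalence=filtered.realized_prevalence,
             unfiltered_prevalence=unfiltered.realized_prevalence)

        # -- screen ------------------------------------------------------
        done = stage("screen")
        screened = screen_sections(filtered, expert_patterns())
        screened.to_jsonl(out / "corpus_screened.jsonl")
        done(retained=len(screened))

        # -- split -------------------------------------------------------
        done = stage("split")
        pool, dev = split_corpus(screened, list(config.split_sizes), seeds["split"])
        pool.to_jsonl(out / "corpus_pool.jsonl")
        dev.to_jsonl(out / "corpus_dev.jsonl")
        done(pool_n=len(pool), dev_n=len(dev))

        # -- train baselines --------------------------------------------
        done = stage("train_gbt")
        gbt = GbtClassifier(seed=seeds["gbt"], **config.gbt_params).fit(screened)
        gbt.save(out / "model_gbt")
        done()
        done = stage("train_dnn")
        dnn = AttentionDnnClassifier(seed=seeds["dnn"], **config.dnn_params).fit(screened)
        dnn.save(out / "model_dnn")
        done(loss_history=[round(x, 4) for x in dnn.loss_history_])

        # -- strategy comparison ----------------------------------------
        done = stage("compare_strategies")
        table, _logs = compare_strategies(config, dev, pool, seeds, out_dir=out)
        table.to_csv(out / "strategy_comparison.csv", index=False)
        valid = table.dropna(subset=["accuracy"])
        best_row = valid.sort_values(
            ["accuracy", "strategy"], ascending=[False, True], kind="stable"
        ).iloc[0]
        best_strategy = str(best_row["strategy"])
        done(best_strategy=best_strategy, best_accuracy=float(best_row["accuracy"]))

        # -- final evaluation on the unfiltered corpus -------------------
        done = stage("final_eval")
        gold = dict(zip(unfiltered.ids, unfiltered.labels))
        final_backend = MockBackend(
            BackendConfig(
                seed=seeds["final_llm"],
                mock_error_rate=config.strategy_error_rates[best_strategy],
            )
        )
        run_strategy = (
            "none" if best_strategy in ("zero_shot", "error_instructions") else best_strategy
        )
        final_template = default_template()
        if best_strategy == "error_instructions":
            # rebuild the instruction paragraph exactly as the winner used it
            final_template = _error_instruction_template(
                config, dev, seeds, final_template
            )
        prior_error_ids = None
        if run_strategy == "targeted":
            probe_cfg = BackendConfig(
                seed=seeds["strategy_pool_probe"],
                mock_error_rate=config.strategy_error_rates.get("zero_shot", 0.1),
            )
            probe_table = llm_label_table(
                run_prompting(MockBackend(probe_cfg), final_template, pool, strategy="none"),
                "negative",
            )
            prior_error_ids = {
                sid for sid, lab in probe_table.items() if lab != pool.by_id(sid).label
            }
        final_entries = run_prompting(
            final_backend,
            final_template,
            unfiltered,
            strategy=run_strategy,
            pool=pool if run_strategy != "none" else None,
            k=config.n_shots,
            seed=seeds["final_llm"],
            prior_error_ids=prior_error_ids,
        )
        replies_to_jsonl(final_entries, out / "replies_final.jsonl")
        gbt_scores = gbt.predict(unfiltered)
        dnn_scores = dnn.predict(unfiltered)
        scores_to_csv(gbt_scores, out / "pred_gbt.csv")
        scores_to_csv(dnn_scores, out / "pred_dnn.csv")
        gbt_table = scores_to_table(gbt_scores)
        dnn_table = scores_to_table(dnn_scores)
        llm_table = llm_label_table(
            final_entries, config.abstention_policy, dnn_table, gbt_table
        )
        with open(out / "pred_llm.csv", "w", encoding="utf-8") as fh:
            fh.write("section_id,label\n")
            for sid in sorted(llm_table):
                fh.write(f"{sid},{llm_table[sid]}\n")
        result = evaluation.ensemble_run([llm_table, dnn_table, gbt_table], gold)
        report = {
            "best_strategy": best_strategy,
            "models": ["llm", "attention_dnn", "gbt"],
            **result.to_dict(),
        }
        (out / "evaluation.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        regions = result.profile.region_counts()
        with open(out / "venn_regions.csv", "w", encoding="utf-8") as fh:
            fh.write("region,count\n")
            for region, count in regions.items():
                fh.write(f"{region},{count}\n")
        done(ensemble_f1=result.metrics.f1, union_errors=result.profile.union_size)

        # -- interpretation ----------------------------------------------
        done = stage("interpret")
        reports = []
        try:
            llm_rep = interpretation.llm_keyword_report(entries_to_replies(final_entries))
            llm_rep.to_csv(out / "keywords_llm.csv")
            reports.append(llm_rep)
        except ValueError as exc:
            log.warning("llm keyword report skipped: %s", exc)
        maps = dnn.attention_maps(unfiltered)
        attn_rep = interpretation.attention_keyword_report(maps)
        attn_rep.to_csv(out / "keywords_attention.csv")
        reports.append(attn_rep)
        gain_rep = interpretation.gain_keyword_report(gbt)
        gain_rep.to_csv(out / "keywords_gain.csv")
        reports.append(gain_rep)
        merged = interpretation.merged_report(reports, load_keywords())
        merged.to_csv(out / "keywords_merged.csv", index=False)
        (out / "keywords_merged.md").write_text(
            interpretation.merged_report_markdown(merged)
        )
        done(n_keywords=len(merged))
    except Exception as exc:
        failed = [s for s in ("simulate", "screen", "split", "train_gbt", "train_dnn",
                              "compare_strategies", "final_eval", "interpret")
                  if s not in manifest["stages"]]
        stage_name = failed[0] if failed else "unknown"
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") from exc

    # -- manifest --------------------------------------------------------
    checksums = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest["checksums"] = checksums
    manifest["metrics"] = report
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    summary = [
        "# Run summary",
        "",
        f"- best prompting strategy (dev accuracy): **{best_strategy}**",
        f"- ensemble F1 on the unfiltered corpus: {result.metrics.as_percent()['f1']}%",
        f"- ensemble precision: {result.metrics.as_percent()['precision']}%",
        f"- ensemble recall: {result.metrics.as_percent()['recall']}%",
        f"- error union across the three models: {result.profile.union_size}",
        f"- mutual errors (all three): {result.profile.abc}",
    ]
    (out / "summary.md").write_text("\n".join(summary) + "\n")
    return manifest
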