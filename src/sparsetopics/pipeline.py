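"""End-to-end orchestration: corpus -> topics -> reports, per period.

``run_pipeline`` executes query filtering, period splitting, language
filtering, duplicate collapsing, matrix construction, topic extraction and
tweets-per-topic model comparison for each period, and writes topic reports,
mention time series, variance curves, the effective configuration and a
structured count log into one output directory. Outputs are deterministic:
rerunning with the same config and seed reproduces the directory byte for
byte (the log records stage counts, never wall-clock times).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import corpus_io, model_selection, preprocess, term_matrix
from .corpus_io import PeriodSplit, QuerySpec, TweetRecord
from .errors import EmptyVocabularyError
from .spca import SpcaConfig, TopicModel, fit_topic_model

__all__ = ["RunConfig", "TopicReportRow", "run_pipeline", "render_topic_table", "report_rows_to_csv"]


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    input_path: str
    out_dir: str
    input_format: str | None = None
    query_path: str | None = None  # None -> packaged default query
    use_query: bool = True
    collapse_hashtags: bool = True
    split: PeriodSplit = field(default_factory=PeriodSplit.default)
    stopword_path: str | None = None
    language: str = "en"
    keep_unknown_lang: bool = True
    min_df: int = 2
    max_df_frac: float = 0.95
    tf_mode: str = "count"
    spca: SpcaConfig = field(default_factory=SpcaConfig)
    settings: tuple[int, ...] = (10, 15, 20)
    threshold: float = 0.90
    top10: bool = False
    mention_bin: str = "day"
    make_plots: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["split"] = {
            "baseline_start": self.split.baseline_start.isoformat(),
            "baseline_end": self.split.baseline_end.isoformat(),
            "followup_start": self.split.followup_start.isoformat(),
            "followup_end": self.split.followup_end.isoformat(),
        }
        return d

    @classmethod
    def from_dict(cls, obj: Mapping) -> "RunConfig":
        obj = dict(obj)
        if "split" in obj and isinstance(obj["split"], Mapping):
            obj["split"] = PeriodSplit(**{k: date.fromisoformat(v) for k, v in obj["split"].items()})
        if "spca" in obj and isinstance(obj["spca"], Mapping):
            obj["spca"] = SpcaConfig(**obj["spca"])
        if "settings" in obj:
            obj["settings"] = tuple(obj["settings"])
        return cls(**obj)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text("utf-8")))


@dataclass(frozen=True)
class TopicReportRow:
    """One topic report line in the summary-table layout.

    ``category`` and ``off_topic_pct`` are emitted blank by design: they are
    the slots a human coder fills during qualitative review, outside the
    computational pipeline.
    """

    topic_index: int
    singular_value: float
    keywords: str  # comma-joined
    n_docs: int
    example_texts: tuple[str, ...]
    category: str = ""
    off_topic_pct: str = ""


def render_topic_table(
    model: TopicModel,
    records_by_id: Mapping[str, TweetRecord],
    *,
    top10: bool = False,
) -> list[TopicReportRow]:
    """One row per topic in extraction order, examples verbatim from the corpus.

    With ``top10`` and more than 10 topics, the 10 largest singular values are
    kept (extraction order preserved within the selection).
    """
    topics = list(model.topics)
    if top10 and len(topics) > 10:
        chosen = sorted(
            sorted(range(len(topics)), key=lambda i: (-topics[i].singular_value, i))[:10]
        )
        topics = [topics[i] for i in chosen]
    rows = []
    for t in topics:
        examples = []
        for did in t.doc_ids:
            if did not in records_by_id:
                raise ValueError(f"topic {t.index} references unknown document id {did!r}")
            examples.append(records_by_id[did].text)
        rows.append(
            TopicReportRow(
                topic_index=t.index,
                singular_value=t.singular_value,
                keywords=", ".join(t.terms),
                n_docs=len(t.doc_ids),
                example_texts=tuple(examples),
            )
        )
    return rows


def report_rows_to_csv(rows: Sequence[TopicReportRow], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "topic": r.topic_index,
                "category": r.category,
                "singular_value": r.singular_value,
                "off_topic_pct": r.off_topic_pct,
                "keywords": r.keywords,
                "n_docs": r.n_docs,
                "example_tweets": " || ".join(r.example_texts),
            }
            for r in rows
        ],
        columns=["topic", "category", "singular_value", "off_topic_pct", "keywords", "n_docs", "example_tweets"],
    )
    df.to_csv(path, index=False)


def _report_rows_to_json(rows: Sequence[TopicReportRow], path: Path) -> None:
    obj = [
        {
            "topic": r.topic_index,
            "category": r.category,
            "singular_value": r.singular_value,
            "off_topic_pct": r.off_topic_pct,
            "keywords": r.keywords,
            "n_docs": r.n_docs,
            "example_tweets": list(r.example_texts),
        }
        for r in rows
    ]
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, ensure_ascii=False) + "\n", encoding="utf-8")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; returns a manifest of written files.

    Stages: read -> query filter -> mention series -> period split -> per
    period: language filter -> duplicate collapse -> matrix -> topic model ->
    report + model comparison. Any stage error propagates after being logged.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_entries: list[dict] = []

    def log(stage: str, **counts) -> None:
        log_entries.append({"stage": stage, **counts})

    def _flush_log() -> None:
        (out / "log.jsonl").write_text(
            "".join(json.dumps(e, sort_keys=True) + "\n" for e in log_entries), encoding="utf-8"
        )

    manifest: dict[str, str] = {}
    try:
        records = corpus_io.read_corpus(config.input_path, config.input_format)
        log("read_corpus", n_records=len(records))

        query = QuerySpec.from_json(config.query_path) if config.query_path else QuerySpec.default()
        if config.use_query:
            matches = corpus_io.filter_by_query(records, query, collapse_hashtags=config.collapse_hashtags)
            filtered = [m.record for m in matches]
        else:
            filtered = list(records)
        log("filter_by_query", n_in=len(records), n_matched=len(filtered))

        series = corpus_io.count_mentions(records, query, config.mention_bin)
        corpus_io.mention_series_to_csv(series, out / "mentions.csv")
        manifest["mentions"] = "mentions.csv"
        log("count_mentions", **{f"total_{s.group}": s.total for s in series})

        baseline, followup, out_of_range = corpus_io.split_periods(filtered, config.split)
        log(
            "split_periods",
            n_baseline=len(baseline),
            n_followup=len(followup),
            n_out_of_range=len(out_of_range),
        )

        policy = (
            preprocess.StopwordPolicy.from_file(config.stopword_path)
            if config.stopword_path
            else preprocess.StopwordPolicy.default()
        )
        records_by_id = {r.id: r for r in records}

        comparison_summary: dict[str, dict] = {}
        for period_name, period_records in (("baseline", baseline), ("followup", followup)):
            kept, excluded = preprocess.filter_language(
                period_records, config.language, keep_unknown=config.keep_unknown_lang
            )
            docs = preprocess.collapse_duplicates(kept, policy)
            log(
                f"preprocess_{period_name}",
                n_records=len(period_records),
                n_kept_language=len(kept),
                n_excluded_language=len(excluded),
                n_documents=len(docs),
                sum_multiplicity=sum(d.multiplicity for d in docs),
            )
            if not docs:
                report_rows_to_csv([], out / f"topics_{period_name}.csv")
                _report_rows_to_json([], out / f"topics_{period_name}.json")
                manifest[f"topics_{period_name}"] = f"topics_{period_name}.csv"
                continue
            try:
                vocab = term_matrix.build_vocabulary(docs, config.min_df, config.max_df_frac)
            except EmptyVocabularyError:
                log(f"term_matrix_{period_name}", n_terms=0)
                report_rows_to_csv([], out / f"topics_{period_name}.csv")
                _report_rows_to_json([], out / f"topics_{period_name}.json")
                manifest[f"topics_{period_name}"] = f"topics_{period_name}.csv"
                continue
            tdm = term_matrix.build_matrix(docs, vocab, config.tf_mode)
            log(f"term_matrix_{period_name}", n_docs=tdm.shape[0], n_terms=tdm.shape[1])

            model = fit_topic_model(tdm, config.spca)
            model.to_json(out / f"model_{period_name}.json")
            rows = render_topic_table(model, records_by_id, top10=config.top10)
            report_rows_to_csv(rows, out / f"topics_{period_name}.csv")
            _report_rows_to_json(rows, out / f"topics_{period_name}.json")
            manifest[f"topics_{period_name}"] = f"topics_{period_name}.csv"
            log(
                f"spca_{period_name}",
                n_topics=len(model.topics),
                explained=(1.0 - model.residual_frob2_after[-1] / model.original_frob2)
                if model.topics
                else 0.0,
            )

            comparison = model_selection.compare_models(
                tdm, config.settings, config.threshold, config.spca
            )
            model_selection.comparison_to_csv(comparison, out / f"curves_{period_name}.csv")
            manifest[f"curves_{period_name}"] = f"curves_{period_name}.csv"
            if config.make_plots:
                model_selection.plot_comparison(
                    comparison, out / f"curves_{period_name}.png", title=f"{period_name} period"
                )
                manifest[f"curves_plot_{period_name}"] = f"curves_{period_name}.png"
            comparison_summary[period_name] = {
                "threshold": comparison.threshold,
                "topics_at_threshold": {str(m): comparison.topics_at_threshold[m] for m in sorted(comparison.curves)},
                "winner": comparison.winner,
            }
            log(f"compare_models_{period_name}", winner=comparison.winner)

        (out / "comparison.json").write_text(
            json.dumps(comparison_summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        manifest["comparison"] = "comparison.json"

        (out / "config.json").write_text(
            json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        manifest["config"] = "config.json"
    except Exception as exc:
        log("error", error=str(exc), type=type(exc).__name__)
        _flush_log()
        raise
    _flush_log()
    manifest["log"] = "log.jsonl"
    return manifest
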