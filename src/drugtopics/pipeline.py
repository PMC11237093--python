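"""End-to-end orchestration: staged runs, caching, run manifest, reports.

A single config tree drives every stage. Each stage writes its artifacts
into the run directory together with a content hash of its inputs and
parameters; re-running with an unchanged config and intact artifacts skips
the stage. The manifest records every parameter, seed and plugin id so
that two runs with identical manifests (and deterministic plugins) produce
identical outputs.
"""

from __future__ import annotations

import csv
import datetime as _dt
import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import corpus as corpus_mod
from . import grouping, labeling, representation, sentiment, synth, topics
from .corpus import Corpus, DrugLexicon, default_lexicon
from .embedding import EmbeddingMatrix, HashingEmbedder, ReducedEmbedding, ReducerParams, embed, reduce

STAGES = (
    "corpus", "embed", "reduce", "topics", "represent", "group", "label",
    "sentiment", "report",
)

DEFAULT_CONFIG: dict = {
    "out_dir": "runs/demo",
    "corpus": {
        "source": "synthetic",  # "synthetic" | "file"
        "path": None,
        "format": None,
        "lexicon": None,  # path to a lexicon CSV; None -> packaged default
        "cutoffs": ["2022-01-01"],
        "synthetic": {},  # SyntheticSpec overrides
    },
    "embedding": {"embedder": "hashing", "d": 384, "seed": 0, "batch_size": 64, "plugin": None},
    "reduction": {
        "k": 5, "n_neighbors": 15, "min_dist": 0.0, "metric": "cosine",
        "seed": 42, "method": "umap",
    },
    "topics": {"min_cluster_size": None, "min_samples": None, "seed": 0},
    "representation": {
        "min_df": 2, "stopwords": "english", "n_keywords": 10,
        "n_representatives": 3, "n_samples": 3, "seed": 0,
    },
    "grouping": {"g_min": 2, "g_max": None, "seed": 0},
    "labeling": {"client": "stub", "excerpt_chars": 500, "replay_path": None},
    "sentiment": {"classifier": "lexicon"},
}


class ConfigError(ValueError):
    pass


def _merge_validate(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = {}
    unknown = [f"{path}{k}" for k in overrides if k not in defaults]
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    for k, dv in defaults.items():
        ov = overrides.get(k, None)
        if isinstance(dv, dict) and k != "synthetic":
            out[k] = _merge_validate(dv, ov or {}, f"{path}{k}.")
        else:
            out[k] = ov if k in overrides else dv
    return out


def load_config(overrides: dict | None = None) -> dict:
    """Merge user overrides into the default config, rejecting unknown keys."""
    cfg = _merge_validate(DEFAULT_CONFIG, overrides or {})
    if cfg["corpus"]["synthetic"]:
        known = {f for f in synth.SyntheticSpec.__dataclass_fields__}
        bad = set(cfg["corpus"]["synthetic"]) - known
        if bad:
            raise ConfigError(f"unknown synthetic spec key(s): {', '.join(sorted(bad))}")
    return cfg


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class PipelineRun:
    """Stage executor bound to a run directory. Artifacts are cached on disk."""

    def __init__(self, config: dict | None = None, force: bool = False):
        self.config = load_config(config)
        self.out_dir = Path(self.config["out_dir"])
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.force = force
        self.manifest_path = self.out_dir / "manifest.json"
        if self.manifest_path.exists() and not force:
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {"config": self.config, "stages": {}}
        self.manifest["config"] = self.config
        self._lexicon: DrugLexicon | None = None

    # -- helpers ---------------------------------------------------------
    def lexicon(self) -> DrugLexicon:
        if self._lexicon is None:
            p = self.config["corpus"]["lexicon"]
            self._lexicon = DrugLexicon.from_csv(p) if p else default_lexicon()
        return self._lexicon

    def _stage_fresh(self, name: str, stage_hash: str, outputs: list[Path]) -> bool:
        rec = self.manifest["stages"].get(name)
        return (
            not self.force
            and rec is not None
            and rec.get("hash") == stage_hash
            and all(p.exists() for p in outputs)
        )

    def _record(self, name: str, stage_hash: str, params: dict, outputs: list[Path], t0: float,
                cached: bool = False, **extra) -> None:
        self.manifest["stages"][name] = {
            "hash": stage_hash,
            "params": params,
            "outputs": [str(p) for p in outputs],
            "elapsed_s": round(time.time() - t0, 3),
            "cached": cached,
            **extra,
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2, default=str))

    def _upstream_hash(self, name: str) -> str:
        rec = self.manifest["stages"].get(name)
        if rec is None:
            raise RuntimeError(f"stage {name!r} has not run; run it first")
        return rec["hash"]

    # -- stages ----------------------------------------------------------
    def stage_corpus(self) -> Corpus:
        cfg = self.config["corpus"]
        if cfg["source"] == "synthetic":
            spec = synth.SyntheticSpec(**cfg["synthetic"])
            upstream = _hash(asdict(spec))
        elif cfg["source"] == "file":
            if not cfg["path"]:
                raise ConfigError("corpus.source=file requires corpus.path")
            upstream = _file_hash(Path(cfg["path"]))
        else:
            raise ConfigError(f"unknown corpus.source {cfg['source']!r}")
        stage_hash = _hash([cfg, upstream])
        corpus_path = self.out_dir / "corpus.jsonl"
        truth_path = self.out_dir / "ground_truth.csv"
        outputs = [corpus_path] + ([truth_path] if cfg["source"] == "synthetic" else [])

        if self._stage_fresh("corpus", stage_hash, outputs):
            c = corpus_mod.load_discussions(corpus_path, "jsonl")
            return corpus_mod.match_terms(corpus_mod.dedupe(c), self.lexicon())

        t0 = time.time()
        if cfg["source"] == "synthetic":
            c, truth = synth.generate_corpus(spec, self.lexicon())
            synth.write_jsonl(c, corpus_path)
            truth.to_csv(truth_path, c.ids())
        else:
            c = corpus_mod.load_discussions(cfg["path"], cfg["format"])
            synth.write_jsonl(c, corpus_path)
        c = corpus_mod.dedupe(c)
        c = corpus_mod.match_terms(c, self.lexicon())
        self._record(
            "corpus", stage_hash, cfg, outputs, t0,
            load_report=c.provenance.get("load_report"),
            dedupe_report={"removed": c.provenance.get("dedupe_report", {}).get("removed", 0)},
            n=len(c),
        )
        return c

    def stage_embed(self, c: Corpus) -> EmbeddingMatrix:
        cfg = self.config["embedding"]
        stage_hash = _hash([cfg, self._upstream_hash("corpus")])
        npy = self.out_dir / "embeddings.npy"
        meta = self.out_dir / "embeddings.meta.json"
        if self._stage_fresh("embed", stage_hash, [npy, meta]):
            m = json.loads(meta.read_text())
            return EmbeddingMatrix(np.load(npy), m["embedder_id"])
        t0 = time.time()
        if cfg["embedder"] == "hashing":
            embedder = HashingEmbedder(d=cfg["d"], seed=cfg["seed"])
        elif cfg["embedder"] == "plugin":
            from .embedding import load_plugin_embedder

            embedder = load_plugin_embedder(cfg["plugin"], batch_size=cfg["batch_size"])
        else:
            raise ConfigError(f"unknown embedder {cfg['embedder']!r}")
        E = embed(c, embedder, batch_size=cfg["batch_size"])
        np.save(npy, E.vectors)
        meta.write_text(json.dumps(
            {"embedder_id": E.embedder_id, "d": E.d, "corpus_hash": self._upstream_hash("corpus")}
        ))
        self._record("embed", stage_hash, cfg, [npy, meta], t0, embedder_id=E.embedder_id)
        return E

    def stage_reduce(self, E: EmbeddingMatrix) -> ReducedEmbedding:
        cfg = self.config["reduction"]
        stage_hash = _hash([cfg, self._upstream_hash("embed")])
        npy = self.out_dir / "reduced.npy"
        params = ReducerParams(
            k=cfg["k"], n_neighbors=cfg["n_neighbors"], min_dist=cfg["min_dist"],
            metric=cfg["metric"], seed=cfg["seed"], method=cfg["method"],
        )
        if self._stage_fresh("reduce", stage_hash, [npy]):
            return ReducedEmbedding(np.load(npy), params)
        t0 = time.time()
        R = reduce(E, params)
        np.save(npy, R.vectors)
        self._record("reduce", stage_hash, cfg, [npy], t0)
        return R

    def stage_topics(self, R: ReducedEmbedding, c: Corpus) -> topics.TopicModel:
        cfg = self.config["topics"]
        stage_hash = _hash([cfg, self._upstream_hash("reduce")])
        csv_path = self.out_dir / "topics.csv"
        model_path = self.out_dir / "topic_model.json"
        if self._stage_fresh("topics", stage_hash, [csv_path, model_path]):
            m = json.loads(model_path.read_text())
            return topics.TopicModel(
                np.array(m["assignment"]), np.array(m["centroids"]), m["init_report"]
            )
        t0 = time.time()
        model = topics.discover_topics(
            R, cfg["min_cluster_size"], cfg["min_samples"], seed=cfg["seed"]
        )
        with open(csv_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["discussion_id", "topic_id"])
            for did, t in zip(c.ids(), model.assignment):
                w.writerow([did, int(t)])
        model_path.write_text(json.dumps(
            {
                "assignment": model.assignment.tolist(),
                "centroids": model.centroids.tolist(),
                "init_report": model.init_report,
            }
        ))
        self._record("topics", stage_hash, cfg, [csv_path, model_path], t0,
                     T=model.T, init_report=model.init_report)
        return model

    def stage_represent(self, c: Corpus, model, R: ReducedEmbedding):
        cfg = self.config["representation"]
        stage_hash = _hash([cfg, self._upstream_hash("topics")])
        cards_path = self.out_dir / "topic_cards.json"
        w_path = self.out_dir / "ctfidf.npz"
        t0 = time.time()
        vocab = representation.build_vocab(
            c, {"min_df": cfg["min_df"], "stopwords": cfg["stopwords"]}
        )
        weights = representation.ctfidf(c, model, vocab)
        if self._stage_fresh("represent", stage_hash, [cards_path, w_path]):
            cards = [representation.TopicCard(**d) for d in json.loads(cards_path.read_text())]
            return weights, cards
        cards = representation.select_exemplars(
            model, R, c, weights,
            n_keywords=cfg["n_keywords"], n_representatives=cfg["n_representatives"],
            n_samples=cfg["n_samples"], seed=cfg["seed"],
        )
        cards_path.write_text(json.dumps([asdict(cd) for cd in cards], indent=2))
        np.savez(w_path, W=weights.W, terms=np.array(vocab.terms))
        self._record("represent", stage_hash, cfg, [cards_path, w_path], t0,
                     vocab_size=len(vocab))
        return weights, cards

    def stage_group(self, weights) -> grouping.GroupModel:
        cfg = self.config["grouping"]
        stage_hash = _hash([cfg, self._upstream_hash("represent")])
        csv_path = self.out_dir / "groups.csv"
        scan_path = self.out_dir / "group_scan.json"
        if self._stage_fresh("group", stage_hash, [csv_path, scan_path]):
            scan = json.loads(scan_path.read_text())
            group_of = np.array([g for _, g in sorted(
                (int(r["topic_id"]), int(r["group_id"]))
                for r in csv.DictReader(open(csv_path))
            )])
            return grouping.GroupModel(
                group_of=group_of, G=scan["G"], silhouette=scan["silhouette"],
                scan=[tuple(x) for x in scan["scan"]], seed=cfg["seed"],
            )
        t0 = time.time()
        T = weights.T
        g_max = cfg["g_max"] if cfg["g_max"] else min(T - 1, 60)
        gm = grouping.group_topics(weights, range(cfg["g_min"], g_max + 1), seed=cfg["seed"])
        with open(csv_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["topic_id", "group_id"])
            for t, g in enumerate(gm.group_of):
                w.writerow([t, int(g)])
        scan_path.write_text(json.dumps(
            {"G": gm.G, "silhouette": gm.silhouette, "scan": gm.scan}
        ))
        self._record("group", stage_hash, cfg, [csv_path, scan_path], t0,
                     G=gm.G, silhouette=gm.silhouette)
        return gm

    def stage_label(self, c: Corpus, cards, gm) -> list[labeling.LabelResult]:
        cfg = self.config["labeling"]
        stage_hash = _hash([cfg, self._upstream_hash("group")])
        out_path = self.out_dir / "labels.csv"
        t0 = time.time()
        if cfg["client"] == "stub":
            # deterministic: label from the topic's own keywords
            client = labeling.StubClient(lambda prompt: _keyword_label(prompt))
        elif cfg["client"] == "replay":
            client = labeling.ReplayClient(cfg["replay_path"])
        else:
            raise ConfigError(f"unknown labeling client {cfg['client']!r}")
        if self._stage_fresh("label", stage_hash, [out_path]):
            return [
                labeling.LabelResult(
                    target=f"{r['target_kind']}:{r['target_id']}",
                    status=r["status"], label=r["label"],
                )
                for r in csv.DictReader(open(out_path))
            ]
        texts_by_id = {d.id: d.text for d in c}
        results = []
        topic_results: dict[int, labeling.LabelResult] = {}
        for card in cards:
            prompt = labeling.build_topic_prompt(
                card, texts_by_id, excerpt_chars=cfg["excerpt_chars"]
            )
            res = labeling.label_with_client(prompt, client, f"topic:{card.topic_id}")
            topic_results[card.topic_id] = res
            results.append(res)
        for g in range(gm.G):
            members = [topic_results[t] for t in np.flatnonzero(gm.group_of == g)]
            try:
                prompt = labeling.build_group_prompt(members)
                results.append(labeling.label_with_client(prompt, client, f"group:{g}"))
            except ValueError as exc:
                results.append(labeling.LabelResult(
                    target=f"group:{g}", status="failed", raw_response=str(exc)
                ))
        with open(out_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["target_kind", "target_id", "status", "label"])
            for r in results:
                kind, tid = r.target.split(":")
                w.writerow([kind, tid, r.status, r.label])
        self._record("label", stage_hash, cfg, [out_path], t0,
                     client=client.name,
                     refused=sum(r.status == "refused" for r in results))
        return results

    def stage_sentiment(self, c: Corpus) -> sentiment.SentimentSummary:
        cfg = self.config["sentiment"]
        stage_hash = _hash([cfg, self._upstream_hash("corpus")])
        res_path = self.out_dir / "sentiment.csv"
        sum_path = self.out_dir / "sentiment_summary.json"
        if self._stage_fresh("sentiment", stage_hash, [res_path, sum_path]):
            s = json.loads(sum_path.read_text())
            return sentiment.SentimentSummary(s["counts"], s["percentages"], s["n_total"])
        t0 = time.time()
        if cfg["classifier"] == "lexicon":
            clf = sentiment.LexiconSentimentClassifier()
        elif cfg["classifier"].startswith("plugin:"):
            clf = sentiment.load_plugin_classifier(cfg["classifier"].split(":", 1)[1])
        else:
            raise ConfigError(f"unknown sentiment classifier {cfg['classifier']!r}")
        results = sentiment.classify_sentiment(c, clf)
        sentiment.results_to_csv(results, res_path)
        summary = sentiment.aggregate_sentiment(results)
        summary.to_json(sum_path)
        self._record("sentiment", stage_hash, cfg, [res_path, sum_path], t0,
                     classifier=clf.name, counts=summary.counts)
        return summary

    def stage_report(self, c: Corpus, R, model, gm) -> dict[str, Path]:
        stage_hash = _hash([self._upstream_hash("group"), self._upstream_hash("sentiment")])
        t0 = time.time()
        lex = self.lexicon()
        files: dict[str, Path] = {}

        heat = corpus_mod.tabulate_term_year(c, lex)
        files["heatmap"] = self.out_dir / "heatmap.csv"
        heat.to_csv(files["heatmap"])

        cutoffs = [_dt.date.fromisoformat(s) for s in self.config["corpus"]["cutoffs"]]
        summary = corpus_mod.summarize(c, lex, cutoffs)
        files["corpus_summary"] = self.out_dir / "corpus_summary.json"
        summary.to_json(files["corpus_summary"])

        files["scatter"] = self.out_dir / "scatter.csv"
        with open(files["scatter"], "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["discussion_id", "x", "y", "topic_id", "group_id"])
            for i, did in enumerate(c.ids()):
                t = int(model.assignment[i])
                w.writerow([
                    did, float(R.vectors[i, 0]),
                    float(R.vectors[i, 1]) if R.k > 1 else 0.0,
                    t, int(gm.group_of[t]),
                ])

        files["topic_table"] = self.out_dir / "topic_table.csv"
        sizes = model.sizes()
        with open(files["topic_table"], "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["topic_id", "size", "group_id"])
            for t in range(model.T):
                w.writerow([t, int(sizes[t]), int(gm.group_of[t])])

        self._record("report", stage_hash, {}, list(files.values()), t0)
        return files


def _keyword_label(prompt: str) -> str:
    """Deterministic stub labeling: echo the prompt's keyword line."""
    for line in prompt.splitlines():
        if line.lower().startswith(("topic keywords:", "topic labels in this theme:")):
            kw = line.split(":", 1)[1].strip()
            if kw:
                return kw.split(",")[0].strip().capitalize() + " discussions"
    return "Unlabeled discussions"


def run_pipeline(config: dict | None = None, force: bool = False) -> dict:
    """Execute every stage in order; return the manifest dict."""
    run = PipelineRun(config, force=force)
    c = run.stage_corpus()
    E = run.stage_embed(c)
    R = run.stage_reduce(E)
    model = run.stage_topics(R, c)
    weights, cards = run.stage_represent(c, model, R)
    gm = run.stage_group(weights)
    run.stage_label(c, cards, gm)
    run.stage_sentiment(c)
    run.stage_report(c, R, model, gm)
    return run.manifest
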