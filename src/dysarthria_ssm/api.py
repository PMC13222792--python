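"""Model-object interface to the severity classifier.

``SpeechSeverityModel`` is constructed from a corpus (manifest + WAV files,
or pre-extracted features); ``fit`` trains the CNN + selective-SSM
classifier under the speaker-disjoint protocol and returns a
``SeverityResults`` carrying the fitted network, training history,
segment- and speaker-level evaluation reports, and a ``summary()`` table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ArrayDataset, CorpusFeatures, build_arrays, extract_corpus
from .evaluation import MetricReport, aggregate_speaker, metrics
from .nn import CNNMambaClassifier, ModelConfig
from .synth import CLASS_ORDER
from .training import (SplitPlan, TrainConfig, TrainResult, class_weights,
                       make_splits, oversample_speaker_blocks, train)


class SpeechSeverityModel:
    """Five-class speech-severity classifier over a speaker-labeled corpus."""

    def __init__(self, corpus: CorpusFeatures,
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None):
        self.corpus = corpus
        self.model_config = model_config or ModelConfig(
            input_size=corpus.size)
        if self.model_config.input_size != corpus.size:
            raise ValueError("model input_size must match the corpus tensor size")
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_manifest(cls, manifest: str | Path | pd.DataFrame,
                      wav_dir: str | Path | None = None,
                      size: int = 128, **kw) -> "SpeechSeverityModel":
        if not isinstance(manifest, pd.DataFrame):
            manifest_path = Path(manifest)
            wav_dir = wav_dir or manifest_path.parent
            manifest = pd.read_csv(manifest_path)
        corpus = extract_corpus(manifest, wav_dir, size=size)
        return cls(corpus, **kw)

    def fit(self, seed: int = 42, splits: SplitPlan | None = None,
            verbose: bool = False) -> "SeverityResults":
        """Train once under a speaker-disjoint train/val/test split."""
        corpus = self.corpus
        speakers = corpus.speakers
        labels_str = np.array([s.label for s in corpus.segments])
        manifest_like = pd.DataFrame(dict(speaker_id=speakers,
                                          label=labels_str))
        plan = splits or make_splits(manifest_like, seed=seed,
                                     mode="train_val_test")
        plan.check_disjoint()
        part_of = np.array([plan.assignment[s] for s in speakers])
        train_mask = part_of == "train"
        ds = build_arrays(corpus, train_mask)

        idx_train = np.flatnonzero(train_mask).tolist()
        idx_train = oversample_speaker_blocks(
            idx_train, speakers.tolist(), labels_str.tolist(),
            self.train_config.balance_target, seed=seed)
        # audit: oversampling must not move speakers across partitions
        assert {speakers[i] for i in idx_train} <= {
            s for s, p in plan.assignment.items() if p == "train"}
        idx_val = np.flatnonzero(part_of == "val")
        idx_test = np.flatnonzero(part_of == "test")

        w = class_weights([labels_str[i] for i in idx_train])
        model = CNNMambaClassifier(self.model_config, seed=seed)
        result = train(model,
                       ds.X[idx_train], ds.y[idx_train],
                       ds.X[idx_val], ds.y[idx_val],
                       self.train_config, seed=seed, weights=w)

        proba = model.predict_proba(ds.X[idx_test])
        pred = np.argmax(proba, axis=1)
        seg_report = metrics(ds.y[idx_test], pred, proba, level="segment")
        spk_reports = {}
        for rule in ("majority", "mean_prob"):
            sids, spk_pred, spk_proba = aggregate_speaker(
                speakers[idx_test], pred, proba, rule=rule)
            spk_truth = np.array([ds.y[idx_test][speakers[idx_test] == s][0]
                                  for s in sids])
            spk_reports[rule] = metrics(spk_truth, spk_pred, spk_proba,
                                        level="speaker", aggregation=rule)
        return SeverityResults(self, model, ds, plan, result, seed,
                               seg_report, spk_reports,
                               idx_test=idx_test, test_pred=pred,
                               test_proba=proba)


@dataclass
class SeverityResults:
    parent: SpeechSeverityModel
    network: CNNMambaClassifier
    dataset: ArrayDataset
    splits: SplitPlan
    train_result: TrainResult
    seed: int
    segment_report: MetricReport
    speaker_reports: dict[str, MetricReport]
    idx_test: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    test_pred: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    test_proba: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def history(self):
        return self.train_result.history

    def metrics_frame(self) -> pd.DataFrame:
        rows = [dict(level="segment", aggregation="none",
                     **self.segment_report.as_dict())]
        for rule, rep in self.speaker_reports.items():
            rows.append(dict(level="speaker", aggregation=rule,
                             **rep.as_dict()))
        return pd.DataFrame(rows)

    def summary(self) -> str:
        buf = io.StringIO()
        hist = self.train_result
        print("Speech severity classification results", file=buf)
        print("=" * 54, file=buf)
        print(f"seed: {self.seed}   best epoch: {hist.best_epoch}   "
              f"best val MCC: {hist.best_val_mcc:.3f}", file=buf)
        print(f"trainable parameters: {self.network.n_parameters():,}",
              file=buf)
        print("-" * 54, file=buf)
        df = self.metrics_frame()
        print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
              file=buf)
        print("-" * 54, file=buf)
        print("speaker-level confusion (majority vote), classes "
              + "/".join(CLASS_ORDER) + ":", file=buf)
        print(self.speaker_reports["majority"].confusion, file=buf)
        return buf.getvalue()
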