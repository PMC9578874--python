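"""End-to-end orchestration: corpus on disk -> features -> ensemble -> metrics.

A corpus directory holds one CSV closure queue per channel per clip, one
WAV file per clip and a ``manifest.csv`` tying them together with labels.
``run_extract`` turns that into the facial-feature table and MFCC
matrices; ``run_end_to_end`` additionally fits the stacking ensemble on a
stratified training split and scores the held-out clips. Every artifact
is stamped with the configuration hash and the seed so reruns are
verifiable: identical config + seed reproduce byte-identical CSV/JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from sklearn.model_selection import train_test_split

from . import metrics as _metrics
from .errors import InvalidArgumentError, InvalidDataError
from .features import StateQueue, facial_features
from .mfcc import AudioClip, MfccConfig, MfccMatrix, mfcc
from .stacking import (
    DEFAULT_FEATURE_SUBSETS,
    FVStackingModel,
    baseline_compare,
)
from .synthetic import SyntheticClip, gen_corpus

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ["clip_id", "blinks", "abt_s", "abti_s", "perclos", "fom", "label"]


@dataclass(frozen=True)
class PipelineConfig:
    """One document with every tunable of the end-to-end flow."""

    fps: float = 25.0
    clip_duration_s: float = 15.0
    audio_duration_s: float = 7.0
    audio_sample_rate: int = 16000
    mfcc: MfccConfig = field(default_factory=MfccConfig)
    k_folds: int = 5
    test_size: float = 0.25
    decision_threshold: float = 0.5
    fom_convention: str = "open_fraction"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "mfcc" in d and isinstance(d["mfcc"], dict):
            d["mfcc"] = MfccConfig(**d["mfcc"])
        return cls(**d)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Disk I/O


def write_queue_csv(queue: StateQueue, path: Path) -> None:
    pd.DataFrame({"frame": np.arange(len(queue)), "state": queue.states}).to_csv(
        path, index=False
    )


def read_queue_csv(path: Path, fps: float, channel: str) -> StateQueue:
    df = pd.read_csv(path)
    return StateQueue(states=df["state"].to_numpy(), fps=fps, channel=channel)


def write_wav(clip: AudioClip, path: Path) -> None:
    pcm = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(path, clip.sample_rate, (pcm * 32767.0).astype(np.int16))


def read_wav(path: Path) -> AudioClip:
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        logger.warning("stereo WAV %s downmixed to mono", path)
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(np.int16).max)
    return AudioClip(samples=np.clip(data, -1.0, 1.0), sample_rate=int(rate))


def write_corpus(clips: list[SyntheticClip], manifest: pd.DataFrame, out_dir: Path) -> Path:
    """Materialise a synthetic corpus: queue CSVs, WAVs and a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for clip, row in zip(clips, manifest.to_dict("records")):
        cid = clip.clip_id
        eye_path, mouth_path = f"{cid}_eye.csv", f"{cid}_mouth.csv"
        wav_path = f"{cid}.wav"
        write_queue_csv(clip.eye_queue, out_dir / eye_path)
        write_queue_csv(clip.mouth_queue, out_dir / mouth_path)
        write_wav(clip.audio, out_dir / wav_path)
        rows.append({**row, "eye_queue": eye_path, "mouth_queue": mouth_path,
                     "audio": wav_path})
    path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def simulate_corpus(n_clips: int, seed: int, out_dir: Path,
                    class_balance: float = 0.5) -> Path:
    clips, manifest = gen_corpus(n_clips, class_balance=class_balance, seed=seed)
    return write_corpus(clips, manifest, out_dir)


# ---------------------------------------------------------------------------
# Extraction


def run_extract(
    config: PipelineConfig, manifest: pd.DataFrame, base_dir: Path
) -> tuple[pd.DataFrame, dict[str, MfccMatrix]]:
    """Per-clip facial feature rows plus MFCC matrices.

    Clips whose audio is missing get a feature row with the voice entry
    absent from the returned mapping; per-clip failures are logged and the
    run continues.
    """
    if len(manifest) == 0:
        raise InvalidArgumentError("empty manifest")
    base_dir = Path(base_dir)
    rows = []
    voices: dict[str, MfccMatrix] = {}
    for rec in manifest.to_dict("records"):
        cid = str(rec["clip_id"])
        try:
            eye = read_queue_csv(base_dir / rec["eye_queue"], config.fps, "eye")
            mouth = read_queue_csv(base_dir / rec["mouth_queue"], config.fps, "mouth")
            fv = facial_features(eye, mouth, fom_convention=config.fom_convention)
        except Exception:  # noqa: BLE001 - per-clip resilience is the contract
            logger.exception("failed to extract facial features for %s", cid)
            continue
        rows.append(
            {
                "clip_id": cid,
                "blinks": fv.blinks,
                "abt_s": fv.abt,
                "abti_s": fv.abti,
                "perclos": fv.perclos,
                "fom": fv.fom,
                "label": int(rec["label"]) if "label" in rec and pd.notna(rec["label"]) else -1,
            }
        )
        audio_rel = rec.get("audio")
        if audio_rel and pd.notna(audio_rel) and (base_dir / str(audio_rel)).exists():
            voices[cid] = mfcc(read_wav(base_dir / str(audio_rel)), config.mfcc)
        else:
            logger.warning("clip %s has no audio; voice features marked absent", cid)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS), voices


def _arrays_from_extracted(
    features: pd.DataFrame, voices: dict[str, MfccMatrix]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    usable = features[features["clip_id"].astype(str).isin(voices)].reset_index(drop=True)
    if len(usable) < len(features):
        logger.warning("dropping %d clip(s) without voice features for the ensemble",
                       len(features) - len(usable))
    if len(usable) == 0:
        raise InvalidDataError("no clips with both modalities available")
    ids = usable["clip_id"].astype(str).tolist()
    facial = usable[["blinks", "abt_s", "abti_s", "perclos", "fom"]].to_numpy(float)
    voice = np.stack([voices[cid].coefficients for cid in ids]).astype(np.float32)
    labels = usable["label"].to_numpy(int)
    return facial, voice, labels, ids


# ---------------------------------------------------------------------------
# End to end


def _stamp(payload: dict, config: PipelineConfig) -> dict:
    payload["config_hash"] = config.config_hash()
    payload["seed"] = config.seed
    return payload


def run_end_to_end(
    config: PipelineConfig,
    corpus_dir: Path,
    out_dir: Path,
    with_baselines: bool = False,
) -> dict:
    """Train the stacking ensemble on a stratified split of the corpus and
    score the held-out clips; writes predictions.csv and metrics.json."""
    corpus_dir, out_dir = Path(corpus_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(corpus_dir / "manifest.csv")
    features, voices = run_extract(config, manifest, corpus_dir)
    facial, voice, labels, ids = _arrays_from_extracted(features, voices)
    if np.unique(labels).size < 2:
        raise InvalidDataError("corpus contains a single class; cannot fit")

    train_idx, test_idx = train_test_split(
        np.arange(labels.size), test_size=config.test_size,
        random_state=config.seed, stratify=labels,
    )
    model = FVStackingModel(facial[train_idx], voice[train_idx], labels[train_idx],
                            clip_ids=[ids[i] for i in train_idx])
    results = model.fit(k_folds=config.k_folds, seed=config.seed)
    results.verify_no_leakage()

    probs, preds = results.predict(facial[test_idx], voice[test_idx],
                                   threshold=config.decision_threshold)
    pred_df = pd.DataFrame(
        {
            "clip_id": [ids[i] for i in test_idx],
            "label": labels[test_idx],
            "probability": probs,
            "prediction": preds,
        }
    ).sort_values("clip_id").reset_index(drop=True)

    m = _metrics.classification_metrics(_metrics.confusion(pred_df["label"], pred_df["prediction"]))
    roc = _metrics.roc_auc(pred_df["label"].to_numpy(), pred_df["probability"].to_numpy())
    metrics_payload = _stamp(
        {
            "n_train": int(train_idx.size),
            "n_test": int(test_idx.size),
            "recall": m["recall"],
            "precision": m["precision"],
            "accuracy": m["accuracy"],
            "f1": m["f1"],
            "auc": roc.auc,
            "metric_flags": list(m["flags"]),
            "base_oof_accuracy": results.oof_base_accuracies(),
        },
        config,
    )
    if with_baselines:
        table = baseline_compare(
            facial, labels, DEFAULT_FEATURE_SUBSETS, seed=config.seed,
            split=(train_idx, test_idx),
        )
        table.to_csv(out_dir / "baselines.csv", index=False)
        metrics_payload["facial_baseline_max_accuracy"] = float(table["accuracy"].max())

    pred_path = out_dir / "predictions.csv"
    pred_df.insert(0, "config_hash", config.config_hash())
    pred_df.to_csv(pred_path, index=False)
    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(metrics_payload, fh, sort_keys=True, indent=2)
        fh.write("\n")
    with open(out_dir / "model.pkl", "wb") as fh:
        pickle.dump(results, fh)
    return metrics_payload


def save_results(results, path: Path) -> None:
    with open(path, "wb") as fh:
        pickle.dump(results, fh)


def load_results(path: Path):
    with open(path, "rb") as fh:
        return pickle.load(fh)
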