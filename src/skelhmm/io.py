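"""On-disk formats, pipeline configuration, and the end-to-end runner.

Formats
-------
* Skeleton CSV: one row per frame with columns ``seq, t, label`` followed by
  ``<joint>_x, <joint>_y, <joint>_z, <joint>_tracked`` for each of the 25
  canonical joint names (units mm). Several sequences share one file,
  distinguished by the ``seq`` column. A JSON-lines dialect carries the
  identical fields, one frame object per line.
* Depth images: 16-bit binary PGM (P5), depths in mm. Foreground masks:
  8-bit PGM with 255 = foreground.
* Observation sequences: one line per sequence, ``label<TAB>s1 s2 ...``
  (tab and label omitted for unlabeled sequences), symbols 1-based.
* Codebooks, models and evaluation reports: JSON.

Every report written by :func:`run_pipeline` embeds the master seed and a
hash of the resolved configuration, so any result can be regenerated from
the report alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import (
    ActionModelSet,
    BaumWelchOptions,
    EvaluationReport,
    evaluate,
    train_action_models,
)
from .depth import DepthImage, ForegroundMask
from .preprocess import FilterParams, extract_keyframes, limit_filter
from .quantize import (
    DEFAULT_JOINT_SUBSET,
    DEFAULT_M,
    Codebook,
    ObservationSequence,
    build_codebook,
    encode,
    extract_features,
)
from .skeleton import JOINT_NAMES, MotionSequence
from .synthetic import NoiseModel, default_library, generate_dataset

logger = logging.getLogger("skelhmm")

# ---------------------------------------------------------------------------
# Skeleton CSV / JSONL
# ---------------------------------------------------------------------------

_JOINT_COLS = [
    f"{name}_{c}" for name in JOINT_NAMES for c in ("x", "y", "z", "tracked")
]


def write_skeleton_csv(seqs, path) -> None:
    """Write one or more motion sequences to the skeleton CSV dialect."""
    if isinstance(seqs, MotionSequence):
        seqs = [seqs]
    rows = []
    for s_idx, seq in enumerate(seqs):
        for i in range(len(seq)):
            row = {"seq": s_idx, "t": int(seq.time_index[i]), "label": seq.label or ""}
            for j, name in enumerate(JOINT_NAMES):
                x, y, z = seq.positions[i, j]
                row[f"{name}_x"] = repr(float(x))
                row[f"{name}_y"] = repr(float(y))
                row[f"{name}_z"] = repr(float(z))
                row[f"{name}_tracked"] = int(seq.tracked[i, j])
            rows.append(row)
    pd.DataFrame(rows, columns=["seq", "t", "label"] + _JOINT_COLS).to_csv(
        path, index=False
    )


def read_skeleton_csv(path) -> list[MotionSequence]:
    """Read motion sequences from the skeleton CSV dialect.

    Raises a ValueError naming any missing joint column, and the offending
    row for a non-monotone time index.
    """
    df = pd.read_csv(path)
    missing = [c for c in ["seq", "t"] + _JOINT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"skeleton CSV {path} is missing columns: {', '.join(missing)}")
    return _frames_to_sequences(df, path)


def _frames_to_sequences(df: pd.DataFrame, origin) -> list[MotionSequence]:
    out = []
    for seq_id, grp in df.groupby("seq", sort=True):
        t = grp["t"].to_numpy()
        if np.any(np.diff(t) <= 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise ValueError(
                f"{origin}: non-monotone time index in sequence {seq_id} at row {bad}"
            )
        T = len(grp)
        pos = np.empty((T, len(JOINT_NAMES), 3))
        trk = np.empty((T, len(JOINT_NAMES)), dtype=bool)
        for j, name in enumerate(JOINT_NAMES):
            for k, c in enumerate(("x", "y", "z")):
                pos[:, j, k] = grp[f"{name}_{c}"].to_numpy(dtype=float)
            trk[:, j] = grp[f"{name}_tracked"].to_numpy(dtype=int).astype(bool)
        label = None
        if "label" in grp.columns:
            lbl = grp["label"].iloc[0]
            label = None if (pd.isna(lbl) or lbl == "") else str(lbl)
        out.append(MotionSequence(positions=pos, tracked=trk, time_index=t, label=label))
    return out


def write_skeleton_jsonl(seqs, path) -> None:
    """JSON-lines dialect: one frame object per line, same fields as CSV."""
    if isinstance(seqs, MotionSequence):
        seqs = [seqs]
    with open(path, "w") as fh:
        for s_idx, seq in enumerate(seqs):
            for i in range(len(seq)):
                rec = {"seq": s_idx, "t": int(seq.time_index[i]), "label": seq.label or ""}
                for j, name in enumerate(JOINT_NAMES):
                    rec[f"{name}_x"] = float(seq.positions[i, j, 0])
                    rec[f"{name}_y"] = float(seq.positions[i, j, 1])
                    rec[f"{name}_z"] = float(seq.positions[i, j, 2])
                    rec[f"{name}_tracked"] = int(seq.tracked[i, j])
                fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_skeleton_jsonl(path) -> list[MotionSequence]:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(json.loads(line))
    df = pd.DataFrame.from_records(records)
    missing = [c for c in ["seq", "t"] + _JOINT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"skeleton JSONL {path} is missing fields: {', '.join(missing)}")
    return _frames_to_sequences(df, path)


# ---------------------------------------------------------------------------
# Depth images (PGM P5) and masks
# ---------------------------------------------------------------------------

def read_depth_pgm(path, invalid_value: float | None = 0.0) -> DepthImage:
    """Read a 16-bit (or 8-bit) binary PGM depth image, depths in mm."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel PGM, got shape {arr.shape}")
    return DepthImage(depth=arr.astype(float), invalid_value=invalid_value)


def write_depth_pgm(image: DepthImage, path) -> None:
    import imageio.v3 as iio

    depth = np.nan_to_num(image.depth, nan=0.0)
    if depth.max() > np.iinfo(np.uint16).max:
        raise ValueError("depth exceeds the 16-bit PGM range")
    iio.imwrite(Path(path), depth.round().astype(np.uint16))


def write_mask_pgm(mask: ForegroundMask, path) -> None:
    """Write a foreground mask as 8-bit PGM, foreground = 255."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), (mask.flags * 255).astype(np.uint8))


def read_mask_pgm(path) -> ForegroundMask:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    return ForegroundMask(flags=(arr > 0).astype(np.uint8))


# ---------------------------------------------------------------------------
# Observation sequences and codebooks
# ---------------------------------------------------------------------------

def write_observations(obs_list, path) -> None:
    with open(path, "w") as fh:
        for obs in obs_list:
            syms = " ".join(str(int(s)) for s in obs.symbols)
            fh.write((f"{obs.label}\t{syms}" if obs.label else syms) + "\n")


def read_observations(path) -> list[ObservationSequence]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            label, _, rest = line.rpartition("\t")
            out.append(
                ObservationSequence(
                    symbols=np.array([int(s) for s in rest.split()]),
                    label=label or None,
                )
            )
    return out


def write_codebook(cb: Codebook, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "centroids": cb.centroids.tolist(),
                "M": cb.M,
                "seed": cb.seed,
                "joint_subset": list(cb.joint_subset),
            },
            fh,
            sort_keys=True,
            indent=1,
        )


def read_codebook(path) -> Codebook:
    with open(path) as fh:
        d = json.load(fh)
    return Codebook(
        centroids=np.asarray(d["centroids"]),
        seed=int(d["seed"]),
        joint_subset=tuple(d["joint_subset"]),
    )


def write_model_set(models: ActionModelSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(models.to_dict(), fh, sort_keys=True, indent=1)


def read_model_set(path) -> ActionModelSet:
    with open(path) as fh:
        return ActionModelSet.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the end-to-end pipeline in one validated bundle.

    Defaults reproduce the standard synthetic benchmark: five action
    classes, 40 sequences per class split in half, T=120 frames, moderate
    sensor noise with sparse spikes.
    """

    seed: int = 7
    # synthetic data
    n_per_class: int = 40
    T: int = 120
    gaussian_sd: float = 3.0
    spike_prob: float = 0.005
    spike_magnitude: float = 150.0
    # filtering
    jitter_radius: float = 5.0
    deviation_radius: float = 50.0
    # keyframes
    use_keyframes: bool = True
    max_error: float = 10.0
    # quantization
    joint_subset: tuple[str, ...] = DEFAULT_JOINT_SUBSET
    M: int = DEFAULT_M
    velocity: bool = False
    # classifier
    N: int = 5
    train_fraction: float = 0.5
    bw_max_iter: int = 100
    bw_tol: float = 1e-4
    bw_floor: float = 1e-6
    # optional input: read sequences from CSV instead of simulating
    input_csv: str | None = None

    def __post_init__(self):
        FilterParams(self.jitter_radius, self.deviation_radius)  # validates
        NoiseModel(self.gaussian_sd, self.spike_prob, self.spike_magnitude)
        if self.max_error < 0:
            raise ValueError("max_error must be >= 0")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.M < 1 or self.N < 1:
            raise ValueError("M and N must be >= 1")
        object.__setattr__(self, "joint_subset", tuple(self.joint_subset))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["joint_subset"] = list(self.joint_subset)
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def _subsequence(seq: MotionSequence, indices: np.ndarray) -> MotionSequence:
    return MotionSequence(
        positions=seq.positions[indices],
        tracked=seq.tracked[indices],
        time_index=seq.time_index[indices],
        label=seq.label,
        frame_rate=seq.frame_rate,
    )


def prepare_observations(
    seqs,
    config: PipelineConfig,
    codebook: Codebook | None = None,
) -> tuple[list[ObservationSequence], Codebook]:
    """filter -> keyframes -> features -> (codebook) -> symbols.

    When ``codebook`` is None, one is built from the pooled features of the
    given sequences (training mode); otherwise the given codebook is applied
    (test mode).
    """
    fparams = FilterParams(config.jitter_radius, config.deviation_radius)
    processed = []
    for seq in seqs:
        filt = limit_filter(seq, fparams)
        if config.use_keyframes:
            kf = extract_keyframes(filt, config.max_error)
            filt = _subsequence(filt, kf.indices)
        processed.append(filt)
    feats = [
        extract_features(s, config.joint_subset, velocity=config.velocity)
        for s in processed
    ]
    if codebook is None:
        codebook = build_codebook(
            np.concatenate(feats),
            M=config.M,
            seed=config.seed,
            joint_subset=config.joint_subset,
        )
    obs = [
        encode(f, codebook, label=s.label) for f, s in zip(feats, processed)
    ]
    return obs, codebook


def train_test_split(seqs, train_fraction: float) -> tuple[list, list]:
    """Deterministic per-class split: the first ``floor(fraction * n)`` of
    each class's sequences (generation/file order) train, the rest test."""
    by_label: dict[str, list] = {}
    for s in seqs:
        by_label.setdefault(s.label, []).append(s)
    train, test = [], []
    for lbl in sorted(by_label):
        group = by_label[lbl]
        k = int(len(group) * train_fraction)
        if k < 1 or k >= len(group):
            raise ValueError(f"train_fraction leaves class {lbl!r} without both splits")
        train.extend(group[:k])
        test.extend(group[k:])
    return train, test


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Execute simulate/ingest -> filter -> keyframes -> encode -> train ->
    evaluate, returning (and optionally writing) a reproducible report."""
    logger.info("pipeline start: seed=%d hash=%s", config.seed, config.config_hash)
    if config.input_csv:
        seqs = read_skeleton_csv(config.input_csv)
        logger.info("ingested %d sequences from %s", len(seqs), config.input_csv)
    else:
        seqs = generate_dataset(
            default_library(),
            n_per_class=config.n_per_class,
            T=config.T,
            noise=NoiseModel(config.gaussian_sd, config.spike_prob, config.spike_magnitude),
            seed=config.seed,
        )
        logger.info("simulated %d sequences (%d per class)", len(seqs), config.n_per_class)

    train_seqs, test_seqs = train_test_split(seqs, config.train_fraction)
    logger.info("split: %d train / %d test", len(train_seqs), len(test_seqs))

    train_obs, codebook = prepare_observations(train_seqs, config)
    test_obs, _ = prepare_observations(test_seqs, config, codebook)
    logger.info("encoded with M=%d codebook", codebook.M)

    models = train_action_models(
        train_obs,
        N=config.N,
        codebook=codebook,
        bw_options=BaumWelchOptions(config.bw_max_iter, config.bw_tol, config.bw_floor),
    )
    logger.info("trained %d class models (N=%d)", len(models.labels), config.N)

    report = evaluate(models, test_obs)
    logger.info("recognition rate: %.4f", report.recognition_rate)

    payload = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "report": report.to_dict(),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_model_set(models, outdir / "models.json")
        with open(outdir / "report.json", "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1)
        logger.info("artifacts written to %s", outdir)
    return payload
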