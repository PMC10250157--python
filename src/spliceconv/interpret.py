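"""Attribution scores and motif summaries for trained models.

Two transparent attribution methods share one output contract (a Z x 4
contribution matrix aligned with the one-hot input):

* ``gradient_x_input`` — gradient of the true-site logit with respect to the
  input, multiplied elementwise by the input; zero-valued input cells score 0.
* ``occlusion`` — for each position, the drop in true-site probability when
  that position's row is zeroed (the N mask); the per-position score is
  placed on the active input cells.

Motif reports aggregate attributions over a sample of true windows and build
a contribution-weighted position frequency matrix (PFM) over the displayed
window (default positions 295-305 inclusive), alongside the plain-frequency
PFM, and export logo-tool-ready inputs (FASTA of the subwindows, PFM TSV).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import EvaluationError, ShapeError
from .models import ArchitectureSpec, ModelWeights, network_with_weights
from . import nn
from .seqdata import (
    BASE_ORDER,
    NucleotideSequence,
    SpliceDataset,
    one_hot_encode,
    write_fasta,
)

AttributionMethod = Literal["gradient_x_input", "occlusion"]


@dataclass
class AttributionMatrix:
    values: np.ndarray  # (Z, 4)
    method: AttributionMethod

    @property
    def position_scores(self) -> np.ndarray:
        """Per-position score: sum of |contribution| across the 4 base channels."""
        return np.abs(self.values).sum(axis=1)


def attribute(
    spec: ArchitectureSpec,
    weights: ModelWeights,
    window: np.ndarray,
    method: AttributionMethod = "gradient_x_input",
) -> AttributionMatrix:
    """Contribution scores of one one-hot window toward the true-site output."""
    x = np.asarray(window, dtype=np.float32)
    if x.shape != (spec.input_len, 4):
        raise ShapeError(f"expected a ({spec.input_len}, 4) window, got {x.shape}")
    values = _attribute_batch(spec, weights, x[None], method)[0]
    return AttributionMatrix(values=values, method=method)


def _attribute_batch(
    spec: ArchitectureSpec,
    weights: ModelWeights,
    x: np.ndarray,
    method: AttributionMethod,
) -> np.ndarray:
    net = network_with_weights(spec, weights)
    if method == "gradient_x_input":
        # forward with caches but no dropout masks, then push the true-site
        # basis vector back through the stack to the input
        rng = np.random.default_rng(0)
        saved_rates = [
            (layer, layer.rate) for layer in net.layers if isinstance(layer, nn.Dropout)
        ]
        for layer, _ in saved_rates:
            layer.rate = 0.0
        logits = net.forward(x, train=True, rng=rng)
        dy = np.zeros_like(logits)
        dy[:, 1] = 1.0  # true_site logit
        dx = net.backward(dy)
        for layer, rate in saved_rates:
            layer.rate = rate
        return (dx * x).astype(np.float64)
    if method == "occlusion":
        out = np.zeros(x.shape, dtype=np.float64)
        base = _true_prob(net, x)
        L = x.shape[1]
        for start in range(0, L, 128):
            stop = min(start + 128, L)
            for i, win in enumerate(x):
                masked = np.repeat(win[None], stop - start, axis=0)
                for j, pos in enumerate(range(start, stop)):
                    masked[j, pos, :] = 0.0
                probs = _true_prob(net, masked)
                drop = base[i] - probs  # positive = position supports true-site call
                out[i, start:stop, :] = drop[:, None] * win[start:stop, :]
        return out
    raise ShapeError(f"unknown attribution method {method!r}")


def _true_prob(net: nn.Network, x: np.ndarray) -> np.ndarray:
    return nn.softmax(net.forward(x, train=False))[:, 1]


@dataclass
class MotifReport:
    window_bounds: tuple[int, int]  # inclusive
    n_sequences: int
    position_importance: np.ndarray  # (Z,) mean |contribution| per position
    pfm: np.ndarray  # (width, 4) contribution-weighted PFM over the window
    frequency_pfm: np.ndarray  # (width, 4) plain base frequencies
    subwindows: list[str]  # sampled subsequences over the window
    method: AttributionMethod = "gradient_x_input"

    @property
    def width(self) -> int:
        return self.window_bounds[1] - self.window_bounds[0] + 1


def motif_report(
    spec: ArchitectureSpec,
    weights: ModelWeights,
    dataset: SpliceDataset,
    n: int = 100,
    window: tuple[int, int] = (295, 305),
    seed: int = 0,
    method: AttributionMethod = "gradient_x_input",
    batch_size: int = 64,
) -> MotifReport:
    """Sample n true windows, aggregate attributions, build the PFMs.

    The contribution-weighted PFM weights each observed base by the positive
    part of its mean signed contribution; a column with no positive signal
    falls back to the plain base frequency so PFM columns always sum to 1.
    """
    lo, hi = window
    if not (0 <= lo <= hi < spec.input_len):
        raise EvaluationError(
            f"window {window} outside the valid range [0, {spec.input_len})"
        )
    true_windows = [w for w in dataset if w.label == "true_site"]
    if not true_windows:
        raise EvaluationError("dataset contains no true-labeled windows")
    if n > len(true_windows):
        raise EvaluationError(
            f"requested {n} sequences but only {len(true_windows)} true windows exist"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(true_windows), size=n, replace=False)
    sampled = [true_windows[i] for i in picks]
    x = np.stack(
        [np.asarray(one_hot_encode(w.bases), dtype=np.float32) for w in sampled]
    )
    attributions = np.zeros((n, spec.input_len, 4), dtype=np.float64)
    for s in range(0, n, batch_size):
        attributions[s : s + batch_size] = _attribute_batch(
            spec, weights, x[s : s + batch_size], method
        )
    position_importance = np.abs(attributions).sum(axis=2).mean(axis=0)
    width = hi - lo + 1
    sub_x = x[:, lo : hi + 1, :]  # (n, width, 4)
    sub_attr = attributions[:, lo : hi + 1, :]
    freq_pfm = sub_x.mean(axis=0).astype(np.float64)
    freq_pfm = _normalize_columns(freq_pfm)
    mean_signed = sub_attr.mean(axis=0)  # (width, 4) mean signed per cell
    weighted = np.maximum(mean_signed, 0.0) * (sub_x.sum(axis=0) > 0)
    pfm = np.zeros_like(weighted)
    for p in range(width):
        total = weighted[p].sum()
        pfm[p] = weighted[p] / total if total > 1e-12 else freq_pfm[p]
    subwindows = [w.bases[lo : hi + 1] for w in sampled]
    return MotifReport(
        window_bounds=(lo, hi),
        n_sequences=n,
        position_importance=position_importance,
        pfm=pfm,
        frequency_pfm=freq_pfm,
        subwindows=subwindows,
        method=method,
    )




def _normalize_columns(pfm: np.ndarray) -> np.ndarray:
    out = pfm.copy()
    for p in range(out.shape[0]):
        total = out[p].sum()
        if total > 1e-12:
            out[p] = out[p] / total
        else:  # all-N column: keep uniform so the PFM stays a probability table
            out[p] = 0.25
    return out


def export_logo_input(
    report: MotifReport,
    path: str | Path,
    fmt: Literal["weighted_fasta", "pfm_tsv"] = "pfm_tsv",
) -> Path:
    """Write logo-generator input: FASTA of subwindows or a PFM TSV."""
    path = Path(path)
    if fmt == "weighted_fasta":
        seqs = [
            NucleotideSequence(s, id=f"motif{i:04d}")
            for i, s in enumerate(report.subwindows)
        ]
        write_fasta(seqs, path)
    elif fmt == "pfm_tsv":
        lo, _ = report.window_bounds
        with open(path, "w") as fh:
            fh.write("pos\t" + "\t".join(BASE_ORDER) + "\n")
            for p in range(report.width):
                row = "\t".join(f"{v:.10f}" for v in report.pfm[p])
                fh.write(f"{lo + p}\t{row}\n")
    else:
        raise EvaluationError(f"unknown export format {fmt!r}")
    return path


def read_pfm_tsv(path: str | Path) -> np.ndarray:
    """Read back a PFM TSV written by :func:`export_logo_input`."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["pos", *BASE_ORDER]:
            raise EvaluationError(f"bad PFM header {header!r}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append([float(v) for v in parts[1:]])
    return np.asarray(rows)
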