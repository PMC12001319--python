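"""Deployment-time adaptation and its evaluation protocols.

At deployment the meta-trained network is frozen.  A *prior bank* holds up
to ``max_priors`` support patients — each an (image, general-model mask,
approved styled mask) triple of the target style.  Adaptation is a single
forward pass conditioned on the bank; the empty bank is the no-adaptation
baseline.  Three protocols are provided:

* :func:`simulate_workflow` — the sequential clinical loop: each new
  patient is predicted with the current bank, scored, and then (after the
  simulated clinician correction, i.e. substituting the styled ground
  truth) joins the bank;
* :func:`sweep_priors` — evaluate a fixed test set at several prior
  counts, the protocol behind prior-count/DSC curves;
* :func:`transfer_baseline` — fine-tune a plain encoder–decoder copy on
  the k styled subjects and evaluate it, for side-by-side comparison with
  prior-guided adaptation at equal data budgets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import autograd as ag
from .grids import Mask, PhantomSubject, Volume
from .metrics import combined_loss, dsc, hausdorff
from .meta_training import StyledTruthCache, TrainConfig
from .network import ModelState, _Net, forward, forward_graph
from .style_ops import StyleTransform

PRED_THRESHOLD = 0.5

SupportTriple = Tuple[Volume, Mask, Mask]


@dataclass
class PriorBank:
    """Ordered support patients of one style (first-in kept on overflow)."""

    style_name: str
    max_priors: int = 10
    entries: List[SupportTriple] = field(default_factory=list)

    def add(self, volume: Volume, general: Mask, styled: Mask) -> bool:
        """Append an entry; returns False (and keeps the earliest entries)
        once the bank is full."""
        if len(self.entries) >= self.max_priors:
            return False
        self.entries.append((volume, general, styled))
        return True

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class EvalCurve:
    """Aggregate metric curve over prior counts plus per-subject records."""

    records: pd.DataFrame  # subject_id, style, n_priors, dsc, hd_mm
    summary: pd.DataFrame  # n_priors, mean_dsc, sd_dsc, mean_hd, sd_hd, n_subjects


def _summarize(records: pd.DataFrame) -> pd.DataFrame:
    grouped = records.groupby("n_priors")
    out = pd.DataFrame(
        {
            "mean_dsc": grouped["dsc"].mean(),
            "sd_dsc": grouped["dsc"].std(ddof=0),
            "mean_hd": grouped["hd_mm"].mean(),
            "sd_hd": grouped["hd_mm"].std(ddof=0),
            "n_subjects": grouped["dsc"].size(),
        }
    ).reset_index()
    return out


def adapt_segment(
    state: ModelState,
    bank: PriorBank,
    query: Tuple[Volume, Mask],
    threshold: float = PRED_THRESHOLD,
) -> Mask:
    """Frozen-weight stylized segmentation of a query patient.

    Thresholds the forward pass at ``threshold``; the empty bank yields
    the no-adaptation output.  Grid congruence between bank and query is
    checked by the forward pass.
    """
    q_vol, q_gen = query
    prob = forward(state, (q_vol, q_gen), bank.entries)
    return Mask(prob > threshold, q_vol.spacing)


def _score(pred: Mask, truth: Mask) -> Tuple[float, float]:
    """DSC always; HD only when both masks are non-empty (else NaN)."""
    d = dsc(pred, truth)
    if pred.is_empty() or truth.is_empty():
        return d, float("nan")
    return d, hausdorff(pred, truth)


def simulate_workflow(
    state: ModelState,
    style: StyleTransform,
    subjects: Sequence[PhantomSubject],
    order_seed: int = 0,
    max_priors: int = 10,
    cache: Optional[StyledTruthCache] = None,
) -> pd.DataFrame:
    """Simulate the sequential clinical adoption of a new style.

    Patients are visited in a seeded order.  Patient 1's styled truth
    (standing in for the clinician's corrected contour) seeds the bank;
    every later patient is first predicted with the current bank and
    scored against its styled truth, which then joins the bank (until
    full).  Returns one record per patient.
    """
    if len(subjects) < 2:
        raise ValueError("workflow simulation needs at least 2 subjects")
    cache = cache or StyledTruthCache()
    rng = np.random.default_rng(order_seed)
    order = rng.permutation(len(subjects))
    bank = PriorBank(style_name=style.name, max_priors=max_priors)
    digest_before = state.digest()
    rows = []
    for patient_no, idx in enumerate(order, start=1):
        s = subjects[int(idx)]
        styled = cache.get(s, style)
        if patient_no == 1:
            bank.add(s.volume, s.general_mask, styled)
            continue
        pred = adapt_segment(state, bank, (s.volume, s.general_mask))
        d, hd = _score(pred, styled)
        rows.append(
            {
                "patient_no": patient_no,
                "subject_id": s.subject_id,
                "style": style.name,
                "n_priors": len(bank),
                "dsc": d,
                "hd_mm": hd,
            }
        )
        bank.add(s.volume, s.general_mask, styled)
    if state.digest() != digest_before:
        raise RuntimeError("model parameters changed during adaptation")
    return pd.DataFrame(rows)


def sweep_priors(
    state: ModelState,
    style: StyleTransform,
    test_subjects: Sequence[PhantomSubject],
    prior_subjects: Sequence[PhantomSubject],
    n_values: Sequence[int] = (0, 1, 3, 5, 10),
    cache: Optional[StyledTruthCache] = None,
) -> EvalCurve:
    """Evaluate every test subject at each prior count (0 = no adaptation).

    Prior subjects must be disjoint from test subjects; for count n the
    first n priors are used, so curves are nested and deterministic.
    """
    test_ids = {s.subject_id for s in test_subjects}
    prior_ids = {s.subject_id for s in prior_subjects}
    if test_ids & prior_ids:
        raise ValueError(f"prior/test subjects overlap: {sorted(test_ids & prior_ids)}")
    n_values = sorted(set(int(n) for n in n_values))
    if n_values and n_values[-1] > len(prior_subjects):
        raise ValueError(
            f"requested {n_values[-1]} priors but only {len(prior_subjects)} available"
        )
    if any(n < 0 for n in n_values):
        raise ValueError("prior counts must be >= 0")
    cache = cache or StyledTruthCache()
    digest_before = state.digest()
    rows = []
    for n in n_values:
        bank = PriorBank(style_name=style.name, max_priors=max(n, 1))
        for s in prior_subjects[:n]:
            bank.add(s.volume, s.general_mask, cache.get(s, style))
        for s in test_subjects:
            pred = adapt_segment(state, bank, (s.volume, s.general_mask))
            d, hd = _score(pred, cache.get(s, style))
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "style": style.name,
                    "n_priors": n,
                    "dsc": d,
                    "hd_mm": hd,
                }
            )
    if state.digest() != digest_before:
        raise RuntimeError("model parameters changed during evaluation")
    records = pd.DataFrame(rows)
    return EvalCurve(records=records, summary=_summarize(records))


def _fit_plain_net(
    state,
    examples,
    steps: int,
    config: TrainConfig,
) -> None:
    """Optimize the backbone (zero style signal) on (subject, target-mask)
    pairs, cycling through them; updates ``state`` in place."""
    optimizer = ag.Adam(state.params, lr=config.learning_rate)
    ema = 0.0
    for step in range(steps):
        s, target = examples[step % len(examples)]
        net = _Net(state, trainable=True)
        pred = forward_graph(net, (s.volume, s.general_mask), ())
        loss = combined_loss(
            pred,
            target.grid[None, None],
            step // max(1, config.epoch_iters),
            ema,
            config.schedule,
            spacing=target.spacing,
        )
        if not np.isfinite(loss.item()):
            raise FloatingPointError(f"non-finite plain-net loss at step {step}")
        loss.backward()
        grads = net.grads()
        if config.clip_norm > 0:
            ag.clip_grad_norm(grads, config.clip_norm)
        optimizer.step(grads)
        ema = 0.9 * ema + 0.1 * dsc(pred.data[0, 0] > PRED_THRESHOLD, target.grid)


def pretrain_plain_segmenter(
    config: TrainConfig,
    subjects: Sequence[PhantomSubject],
    steps: int = 300,
    seed: int = 0,
) -> ModelState:
    """Train a plain encoder–decoder (no difference path) as a general
    whole-structure segmenter: (image, general mask) → anatomical target.

    This is the in-package stand-in for a pre-trained segmentation
    network, and the starting point for transfer-learning comparisons.
    """
    from .network import init_state

    state = init_state(config.arch(), seed=seed)
    rng = np.random.default_rng(seed)
    order = [int(i) for i in rng.permutation(len(subjects))]
    examples = [(subjects[i], subjects[i].structures.target) for i in order]
    _fit_plain_net(state, examples, steps, config)
    return state


def transfer_baseline(
    plain_state,
    style: StyleTransform,
    tune_subjects: Sequence[PhantomSubject],
    test_subjects: Sequence[PhantomSubject],
    config: TrainConfig,
    tuning_steps: int = 100,
    cache: Optional[StyledTruthCache] = None,
) -> Tuple[EvalCurve, str]:
    """Transfer-learning comparison: fine-tune a plain encoder–decoder.

    ``plain_state`` is the pre-trained general segmenter (see
    :func:`pretrain_plain_segmenter`) — deliberately *not* the
    meta-trained model, so the comparison contrasts "pre-trained net +
    fine-tuning" against "meta-learner + priors" at equal style-data
    budgets.  All layers of a copy are fine-tuned with the combined loss
    on the k styled tuning subjects for ``tuning_steps`` optimizer steps,
    then evaluated on the test subjects.  Returns the evaluation curve
    (x-axis = k, aligned with ``sweep_priors`` n) and the tuned copy's
    digest (which differs from the starting state's).
    """
    if len(tune_subjects) < 1:
        raise ValueError("transfer tuning needs at least one subject")
    cache = cache or StyledTruthCache()
    tuned = plain_state.copy()
    examples = [(s, cache.get(s, style)) for s in tune_subjects]
    _fit_plain_net(tuned, examples, tuning_steps, config)
    k = len(tune_subjects)
    rows = []
    for s in test_subjects:
        pred_grid = forward(tuned, (s.volume, s.general_mask), ())
        pred = Mask(pred_grid > PRED_THRESHOLD, s.volume.spacing)
        d, hd = _score(pred, cache.get(s, style))
        rows.append(
            {
                "subject_id": s.subject_id,
                "style": style.name,
                "n_priors": k,
                "dsc": d,
                "hd_mm": hd,
            }
        )
    records = pd.DataFrame(rows)
    return EvalCurve(records=records, summary=_summarize(records)), tuned.digest()
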