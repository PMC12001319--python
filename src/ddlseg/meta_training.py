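"""Episodic meta-training of the style-adaptation network.

One training iteration = one episode = one optimizer step (batch size 1):
a style is drawn uniformly from the training-style list, a support count k
uniformly from {1..max_priors}, and k+1 subjects are sampled without
replacement; the query's styled truth is the target of the combined
Dice + Hausdorff-surrogate loss, and encoder, difference block and decoder
are all updated.  The anatomical (unstyled) truth is never a training
target — only styled truths — since the style delta is what is learned.

The loss-schedule "epoch" is a fixed number of iterations (the phantom pool
is unbounded, so a dataset-pass epoch does not transfer).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import autograd as ag
from .grids import Mask, PhantomSubject, Volume
from .metrics import LossSchedule, combined_loss, dsc
from .network import ArchSpec, ModelState, _Net, forward_graph, init_state
from .style_ops import (
    HELDOUT_STYLE_NAMES,
    TRAIN_STYLE_NAMES,
    StyleTransform,
    apply_style,
    get_style,
)

SupportTriple = Tuple[Volume, Mask, Mask]  # (image, general M, styled truth P)


@dataclass(frozen=True)
class Episode:
    """One meta-training sample: a query plus k support triples, all
    carrying the same style."""

    style_name: str
    query: SupportTriple
    supports: Tuple[SupportTriple, ...]
    query_id: str
    support_ids: Tuple[str, ...]

    def __post_init__(self):
        if self.query_id in self.support_ids:
            raise ValueError("query subject must not appear among supports")


@dataclass(frozen=True)
class TrainConfig:
    """Reference (desk-scale) meta-training configuration.

    ``batch_size`` is fixed at one episode per optimizer step.  Train and
    eval style lists must be disjoint (held-out style protocol).
    """

    iterations: int = 1500
    learning_rate: float = 1e-3
    max_priors: int = 10
    seed: int = 0
    base_features: int = 8
    shape: Tuple[int, int, int] = (24, 24, 24)
    spacing: Tuple[float, float, float] = (2.0, 1.17, 1.17)
    noise_sd: float = 6.0
    n_subjects: int = 40
    epoch_iters: int = 50
    clip_norm: float = 5.0  # global gradient-norm clip (0 disables)
    schedule: LossSchedule = field(default_factory=LossSchedule)
    train_styles: Tuple[str, ...] = TRAIN_STYLE_NAMES
    eval_styles: Tuple[str, ...] = HELDOUT_STYLE_NAMES
    batch_size: int = 1

    def __post_init__(self):
        if not self.train_styles or not self.eval_styles:
            raise ValueError("train and eval style lists must be non-empty")
        clash = set(self.train_styles) & set(self.eval_styles)
        if clash:
            raise ValueError(f"train/eval style lists overlap: {sorted(clash)}")
        if self.batch_size != 1:
            raise ValueError("batch size is fixed at 1")

    def arch(self) -> ArchSpec:
        return ArchSpec(base_features=self.base_features)


def draw_style_and_k(rng: np.random.Generator, config: "TrainConfig") -> Tuple[str, int]:
    """One iteration's draw: style uniform over the training list, support
    count k uniform on {1..max_priors}."""
    style_name = config.train_styles[int(rng.integers(0, len(config.train_styles)))]
    k = int(rng.integers(1, config.max_priors + 1))
    return style_name, k


class StyledTruthCache:
    """Lazily computed styled ground truths per (subject, style)."""

    def __init__(self):
        self._cache: Dict[Tuple[str, str], Mask] = {}

    def get(self, subject: PhantomSubject, style: StyleTransform) -> Mask:
        key = (subject.subject_id, style.name)
        if key not in self._cache:
            self._cache[key] = apply_style(style, subject.structures)
        return self._cache[key]


def build_episode(
    subjects: Sequence[PhantomSubject],
    style: StyleTransform,
    k: int,
    seed: int,
    cache: Optional[StyledTruthCache] = None,
) -> Episode:
    """Seeded sampling (without replacement) of 1 query + k supports."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(subjects) < k + 1:
        raise ValueError(f"need at least {k + 1} subjects, got {len(subjects)}")
    cache = cache or StyledTruthCache()
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(subjects), size=k + 1, replace=False)
    chosen = [subjects[int(i)] for i in picks]

    def triple(s: PhantomSubject) -> SupportTriple:
        return (s.volume, s.general_mask, cache.get(s, style))

    return Episode(
        style_name=style.name,
        query=triple(chosen[0]),
        supports=tuple(triple(s) for s in chosen[1:]),
        query_id=chosen[0].subject_id,
        support_ids=tuple(s.subject_id for s in chosen[1:]),
    )


def train_step(
    state: ModelState,
    episode: Episode,
    epoch: int,
    running_dsc: float,
    config: TrainConfig,
    optimizer: Optional[ag.Adam] = None,
) -> Tuple[ModelState, float, float]:
    """One Adam update of encoder + DDL block + decoder.

    Updates ``state.params`` in place (its digest changes) and returns
    ``(state, loss, batch_dsc)``.  Raises FloatingPointError on a
    non-finite loss.
    """
    optimizer = optimizer or ag.Adam(state.params, lr=config.learning_rate)
    net = _Net(state, trainable=True)
    q_vol, q_gen, q_styled = episode.query
    pred = forward_graph(net, (q_vol, q_gen), episode.supports)
    target = q_styled.grid[None, None]
    loss = combined_loss(
        pred, target, epoch, running_dsc, config.schedule, spacing=q_styled.spacing
    )
    loss_val = loss.item()
    if not np.isfinite(loss_val):
        raise FloatingPointError(
            f"non-finite loss at epoch {epoch} on episode "
            f"(style={episode.style_name}, query={episode.query_id})"
        )
    loss.backward()
    grads = net.grads()
    if config.clip_norm > 0:
        ag.clip_grad_norm(grads, config.clip_norm)
    optimizer.step(grads)
    batch_dsc = dsc(pred.data[0, 0] > 0.5, q_styled.grid)
    return state, loss_val, batch_dsc


@dataclass
class TrainOutput:
    state: ModelState
    trace: pd.DataFrame  # iteration, style, k, loss, dsc, running_dsc, hd_weight
    drawn_styles: Tuple[str, ...]


def train(
    config: TrainConfig,
    subjects: Sequence[PhantomSubject],
    callback=None,
) -> TrainOutput:
    """Run the full episodic meta-training loop, reproducibly.

    Every drawn style is logged; the held-out protocol (no eval style ever
    sampled) is asserted on each iteration.
    """
    if len(subjects) < config.max_priors + 1:
        raise ValueError(
            f"subject pool of {len(subjects)} cannot host episodes with up to "
            f"{config.max_priors} supports; provide at least {config.max_priors + 1}"
        )
    rng = np.random.default_rng(config.seed)
    state = init_state(config.arch(), seed=int(rng.integers(0, 2**31 - 1)))
    optimizer = ag.Adam(state.params, lr=config.learning_rate)
    cache = StyledTruthCache()
    eval_set = set(config.eval_styles)
    ema = 0.0
    rows = []
    drawn: List[str] = []
    for it in range(config.iterations):
        style_name, k = draw_style_and_k(rng, config)
        assert style_name not in eval_set, "held-out style drawn during training"
        drawn.append(style_name)
        style = get_style(style_name)
        ep_seed = int(rng.integers(0, 2**31 - 1))
        episode = build_episode(subjects, style, k, ep_seed, cache=cache)
        epoch = it // config.epoch_iters
        state, loss_val, batch_dsc = train_step(
            state, episode, epoch, ema, config, optimizer=optimizer
        )
        ema = 0.9 * ema + 0.1 * batch_dsc
        rows.append(
            {
                "iteration": it,
                "style": style_name,
                "k": k,
                "loss": loss_val,
                "dsc": batch_dsc,
                "running_dsc": ema,
                "hd_weight": config.schedule.weight(epoch, ema),
            }
        )
        if callback is not None:
            callback(it, rows[-1])
    return TrainOutput(state=state, trace=pd.DataFrame(rows), drawn_styles=tuple(drawn))
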