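"""Model/Results facade over the meta-training and adaptation machinery.

Follows the fitted-model idiom: :class:`PriorGuidedDDL` is constructed
from data (phantom subjects + style lists + a training configuration), its
:meth:`~PriorGuidedDDL.fit` runs episodic meta-training and returns a
:class:`DDLResults` carrying the trained parameters, the training trace
and a ``summary()``; adaptation, evaluation sweeps and the transfer
baseline hang off the results object.

Example
-------
>>> from ddlseg import generate_cohort
>>> from ddlseg.model import PriorGuidedDDL
>>> from ddlseg.meta_training import TrainConfig
>>> subjects = generate_cohort(40, seed=100)
>>> model = PriorGuidedDDL(subjects, config=TrainConfig(iterations=1500, seed=1))
>>> res = model.fit()
>>> print(res.summary())                        # doctest: +SKIP
>>> curve = res.sweep_priors("test_superior_half",
...                          generate_cohort(8, seed=900),
...                          generate_cohort(10, seed=950))   # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple, Union

import pandas as pd

from . import adaptation as ad
from .grids import Mask, PhantomSubject, Volume
from .io import load_checkpoint, save_checkpoint
from .meta_training import StyledTruthCache, TrainConfig, train
from .network import ModelState
from .style_ops import StyleTransform, get_style


def _resolve_style(style: Union[str, StyleTransform]) -> StyleTransform:
    return get_style(style) if isinstance(style, str) else style


class PriorGuidedDDL:
    """Prior-guided deep difference learner, built from a subject pool.

    Parameters
    ----------
    subjects
        Training pool of phantom subjects (or any objects with the same
        volume / general-mask / structures interface).
    config
        :class:`~ddlseg.meta_training.TrainConfig`; holds the architecture
        scale, iteration budget, seed and the train/eval style lists.
    """

    def __init__(
        self,
        subjects: Sequence[PhantomSubject],
        config: Optional[TrainConfig] = None,
    ):
        self.subjects = list(subjects)
        self.config = config or TrainConfig()
        if len(self.subjects) < self.config.max_priors + 1:
            raise ValueError(
                f"need at least max_priors+1={self.config.max_priors + 1} "
                f"subjects, got {len(self.subjects)}"
            )

    @classmethod
    def from_phantoms(
        cls,
        n_subjects: int = 40,
        seed: int = 100,
        config: Optional[TrainConfig] = None,
    ) -> "PriorGuidedDDL":
        """Generate a seeded phantom cohort matching the config's grid."""
        from .phantom import generate_cohort

        config = config or TrainConfig()
        subjects = generate_cohort(
            n_subjects,
            seed=seed,
            shape=config.shape,
            spacing=config.spacing,
            noise_sd=config.noise_sd,
        )
        return cls(subjects, config=config)

    def fit(self, seed: Optional[int] = None, callback=None) -> "DDLResults":
        """Run episodic meta-training; returns the fitted results."""
        config = self.config if seed is None else replace(self.config, seed=seed)
        out = train(config, self.subjects, callback=callback)
        return DDLResults(model=self, state=out.state, trace=out.trace, config=config)


class DDLResults:
    """Fitted meta-learner: frozen parameters + training diagnostics.

    All adaptation/evaluation methods are inference-only; the parameter
    digest is asserted unchanged across them.
    """

    def __init__(
        self,
        model: Optional[PriorGuidedDDL],
        state: ModelState,
        trace: Optional[pd.DataFrame],
        config: TrainConfig,
    ):
        self.model = model
        self.state = state
        self.trace = trace if trace is not None else pd.DataFrame()
        self.config = config
        self._cache = StyledTruthCache()
        self._plain_state = None

    # -- diagnostics -------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Prior-guided deep difference learner — fit summary",
            "=" * 52,
            f"architecture          base {self.state.arch.base_features} features, "
            f"{self.state.arch.pool_steps} pool steps, atrous {self.state.arch.atrous_rates}",
            f"parameters            {self.state.n_parameters():,}",
            f"digest                {self.state.digest()[:16]}…",
            f"iterations            {len(self.trace)}",
            f"max priors            {self.config.max_priors}",
            f"train styles          {len(self.config.train_styles)}",
            f"held-out styles       {len(self.config.eval_styles)}",
        ]
        if len(self.trace):
            dec = max(1, len(self.trace) // 10)
            lines += [
                f"loss  first→last     {self.trace.loss.head(dec).mean():.3f} → "
                f"{self.trace.loss.tail(dec).mean():.3f}   (decile means)",
                f"batch DSC first→last {self.trace.dsc.head(dec).median():.3f} → "
                f"{self.trace.dsc.tail(dec).median():.3f}   (decile medians)",
            ]
        return "\n".join(lines)

    # -- adaptation / evaluation --------------------------------------------
    def adapt_segment(
        self, bank: ad.PriorBank, query: Tuple[Volume, Mask]
    ) -> Mask:
        return ad.adapt_segment(self.state, bank, query)

    def simulate_workflow(
        self,
        style: Union[str, StyleTransform],
        subjects: Sequence[PhantomSubject],
        order_seed: int = 0,
    ) -> pd.DataFrame:
        return ad.simulate_workflow(
            self.state,
            _resolve_style(style),
            subjects,
            order_seed=order_seed,
            max_priors=self.config.max_priors,
            cache=self._cache,
        )

    def sweep_priors(
        self,
        style: Union[str, StyleTransform],
        test_subjects: Sequence[PhantomSubject],
        prior_subjects: Sequence[PhantomSubject],
        n_values: Sequence[int] = (0, 1, 3, 5, 10),
    ) -> ad.EvalCurve:
        return ad.sweep_priors(
            self.state,
            _resolve_style(style),
            test_subjects,
            prior_subjects,
            n_values,
            cache=self._cache,
        )

    def plain_segmenter(self, pretrain_steps: int = 300, seed: int = 0):
        """Pre-train (once, cached) the plain general segmenter used as
        the transfer-learning starting point."""
        if getattr(self, "_plain_state", None) is None:
            if self.model is None:
                raise ValueError(
                    "transfer baseline needs the training subject pool; "
                    "results loaded from a checkpoint carry none"
                )
            self._plain_state = ad.pretrain_plain_segmenter(
                self.config, self.model.subjects, steps=pretrain_steps, seed=seed
            )
        return self._plain_state

    def transfer_baseline(
        self,
        style: Union[str, StyleTransform],
        tune_subjects: Sequence[PhantomSubject],
        test_subjects: Sequence[PhantomSubject],
        tuning_steps: int = 100,
        pretrain_steps: int = 300,
    ) -> Tuple[ad.EvalCurve, str]:
        return ad.transfer_baseline(
            self.plain_segmenter(pretrain_steps=pretrain_steps),
            _resolve_style(style),
            tune_subjects,
            test_subjects,
            self.config,
            tuning_steps=tuning_steps,
            cache=self._cache,
        )

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        save_checkpoint(self.state, path)

    @classmethod
    def load(cls, path, config: Optional[TrainConfig] = None) -> "DDLResults":
        config = config or TrainConfig()
        state = load_checkpoint(path)
        return cls(model=None, state=state, trace=None, config=config)
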