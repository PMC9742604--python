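"""Adversarial training of the generator, discriminator and classifier.

Five losses drive the model: an L1 reconstruction loss pulling the generated
ROI series F_g toward the empirical series F_e; least-squares adversarial
losses for the generator and the multi-channel discriminator; a two-path
cross-entropy classification loss evaluated on both the learned (A_g, F_g)
and the empirical (A_e, F_e) pair; and a Frobenius-norm penalty on the
connectivity-learning transform W.  The hybrid cost is
``L_all = L_rec + L_g + L_d + L_cls + lambda * L_reg``.

Each batch is processed in three sub-steps: (a) the discriminator descends
L_d; (b) the generator (RFLNet + SAT) descends L_g + L_rec; (c) with the
generator frozen, the connectivity learner and classifier descend
L_cls + lambda * L_reg.  All three use Adam; the discriminator runs at 4x
the generator/classifier learning rate.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from ._autodiff import Tensor, no_grad
from ._nn import DTYPE, Adam, BatchNorm3d, Module
from .connectivity import ConnectivityLearner
from .gcc import GCC, GCCConfig, normalize_adjacency, rescale_pearson
from .mtd import MTD
from .phantom import Subject
from .rflnet import RFLNet, RFLNetConfig
from .sat import SAT, SATConfig

__all__ = [
    "ModelConfig", "TrainConfig", "LossReport", "ATATModel", "Trainer",
    "loss_rec", "loss_g", "loss_d", "loss_cls", "loss_reg",
]

_PROB_FLOOR = 1e-12


# ------------------------------------------------------------------- losses

def loss_rec(f_g: Tensor, f_e: np.ndarray | Tensor, norm: str = "l1") -> Tensor:
    """Reconstruction loss ||F_g - F_e|| between generated and empirical series.

    ``norm`` selects the matrix norm: ``"l1"`` (entrywise sum of absolute
    deviations, the default), ``"frobenius"``, or ``"mean_l1"`` (mean absolute
    deviation, i.e. the MAE metric itself).  The entrywise L1 norm keeps the
    reconstruction gradient on the same footing as the adversarial term, which
    a per-entry mean would shrink by a factor N*q.
    """
    if not isinstance(f_e, Tensor):
        f_e = Tensor(np.asarray(f_e, dtype=DTYPE))
    diff = f_g - f_e
    if norm == "l1":
        return diff.abs().sum()
    if norm == "frobenius":
        return ((diff * diff).sum() + 1e-24).sqrt()
    if norm == "mean_l1":
        return diff.abs().mean()
    raise ValueError(f"unknown reconstruction norm {norm!r}")


def _mean(values: list[Tensor]) -> Tensor:
    total = values[0]
    for v in values[1:]:
        total = total + v
    return total * (1.0 / len(values))


def loss_g(d_fake: list[Tensor]) -> Tensor:
    """E[(1 - D(G(X)))^2]; zero iff every fake score is 1."""
    return _mean([(1.0 - d) ** 2.0 for d in d_fake])


def loss_d(d_fake: list[Tensor], d_real: list[Tensor]) -> Tensor:
    """E[D(G(X))^2] + E[(1 - D(F_e))^2]; zero iff fakes score 0 and reals 1."""
    return _mean([d ** 2.0 for d in d_fake]) + _mean([(1.0 - d) ** 2.0 for d in d_real])


def loss_cls(probs_generated: list[Tensor], probs_empirical: list[Tensor],
             class_indices: list[int]) -> Tensor:
    """Summed cross-entropy of both classifier paths, averaged over the batch."""
    terms = []
    for p_g, p_e, y in zip(probs_generated, probs_empirical, class_indices):
        terms.append(-(p_g[y].clip_min(_PROB_FLOOR).log())
                     - (p_e[y].clip_min(_PROB_FLOOR).log()))
    return _mean(terms)


def loss_reg(weight: Tensor) -> Tensor:
    """Frobenius norm of the connectivity-learning transform."""
    return ((weight * weight).sum()).sqrt()


# -------------------------------------------------------------------- model

@dataclass
class ModelConfig:
    grid_shape: tuple[int, int, int]
    n_rois: int
    n_timepoints: int
    n_blocks: int = 4
    channels: tuple[int, ...] = (8, 16, 32, 64)
    n_heads: int = 11
    sigma: float = 2.0
    n_classes: int = 2
    seed: int = 0


class ATATModel(Module):
    """Generator (RFLNet + SAT + CL), discriminator (MTD) and classifier (GCC)."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        rngs = [np.random.default_rng(s) for s in ss.spawn(5)]
        self.rflnet = RFLNet(
            RFLNetConfig(grid_shape=tuple(config.grid_shape), n_rois=config.n_rois,
                         n_timepoints=config.n_timepoints, n_blocks=config.n_blocks,
                         channels=tuple(config.channels)), rngs[0])
        self.sat = SAT(SATConfig(n_timepoints=config.n_timepoints,
                                 n_heads=config.n_heads), rngs[1])
        self.cl = ConnectivityLearner(config.n_timepoints, rngs[2], sigma=config.sigma)
        self.mtd = MTD(config.n_rois, config.n_timepoints, rngs[3])
        self.gcc = GCC(GCCConfig(n_rois=config.n_rois,
                                 n_timepoints=config.n_timepoints,
                                 n_classes=config.n_classes), rngs[4])
        self.classes_: list[int] = list(range(config.n_classes))

    # ------------------------------------------------------------- forward
    def generate(self, volume: np.ndarray, embeddings: np.ndarray) -> Tensor:
        """4-D volume -> generated ROI time series F_g (differentiable)."""
        f1 = self.rflnet(volume, embeddings)
        return self.sat(f1, embeddings)

    def construct(self, subject: Subject) -> np.ndarray:
        """Inference: subject -> learned connectivity matrix A_g."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                f_g = self.generate(subject.volume, subject.embeddings)
                a_g = self.cl(f_g)
            return np.asarray(a_g.data, dtype=np.float64)
        finally:
            if was_training:
                self.train()

    def predict_proba(self, subject: Subject, path: str = "generated") -> np.ndarray:
        """Class probabilities from the generated (default) or empirical path."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                if path == "generated":
                    f_g = self.generate(subject.volume, subject.embeddings)
                    a_g = self.cl(f_g)
                    probs = self.gcc(a_g, f_g)
                elif path == "empirical":
                    probs = self.gcc(rescale_pearson(subject.a_e), subject.f_e)
                else:
                    raise ValueError(f"unknown path {path!r}")
            return np.asarray(probs.data, dtype=np.float64)
        finally:
            if was_training:
                self.train()

    def predict(self, subject: Subject, path: str = "generated") -> int:
        probs = self.predict_proba(subject, path=path)
        return self.classes_[int(np.argmax(probs))]

    # ----------------------------------------------------------- persistence
    def _batchnorms(self) -> list[BatchNorm3d]:
        return list(self.rflnet.norms)

    def save(self, path) -> None:
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        for j, bn in enumerate(self._batchnorms()):
            arrays[f"bn_mean_{j}"] = bn.running_mean
            arrays[f"bn_var_{j}"] = bn.running_var
        arrays["config_json"] = np.frombuffer(
            json.dumps({**asdict(self.config), "classes_": self.classes_})
            .encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ATATModel":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["config_json"]).decode())
            classes = cfg.pop("classes_")
            cfg["grid_shape"] = tuple(cfg["grid_shape"])
            cfg["channels"] = tuple(cfg["channels"])
            model = cls(ModelConfig(**cfg))
            for i, p in enumerate(model.parameters()):
                p.data = np.array(data[f"param_{i}"])
            for j, bn in enumerate(model._batchnorms()):
                bn.running_mean = np.array(data[f"bn_mean_{j}"])
                bn.running_var = np.array(data[f"bn_var_{j}"])
        model.classes_ = [int(c) for c in classes]
        return model


# ----------------------------------------------------------------- training

@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 2
    lr_generator: float = 1e-4
    lr_classifier: float = 1e-4
    lr_discriminator: float = 4e-4
    lambda_reg: float = 1e-5
    rec_norm: str = "l1"
    classifier_refine_steps: int = 0
    seed: int = 0

    def validate(self) -> None:
        if min(self.lr_generator, self.lr_classifier, self.lr_discriminator) <= 0:
            raise ValueError("learning rates must be positive")
        if self.lambda_reg < 0:
            raise ValueError("lambda must be nonnegative")


@dataclass
class LossReport:
    step: int
    l_rec: float
    l_g: float
    l_d: float
    l_cls: float
    l_reg: float
    l_all: float
    mae: float = field(default=float("nan"))


class NonFiniteLossError(RuntimeError):
    pass


class Trainer:
    """Alternating optimization of the three players on a labelled cohort."""

    def __init__(self, model: ATATModel, subjects: list[Subject], config: TrainConfig):
        config.validate()
        self.model = model
        self.subjects = subjects
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        gen_params = list(model.rflnet.parameters()) + list(model.sat.parameters())
        cls_params = list(model.cl.parameters()) + list(model.gcc.parameters())
        self.opt_gen = Adam(gen_params, lr=config.lr_generator)
        self.opt_disc = Adam(list(model.mtd.parameters()), lr=config.lr_discriminator)
        self.opt_cls = Adam(cls_params, lr=config.lr_classifier)
        labels = sorted({s.label for s in subjects})
        if len(labels) > model.config.n_classes:
            raise ValueError("more labels than classifier heads")
        model.classes_ = labels + [c for c in model.classes_ if c not in labels][
            : model.config.n_classes - len(labels)]
        self._class_index = {lab: i for i, lab in enumerate(model.classes_)}
        # empirical features are fixed: precompute tensors / normalized FBNs
        self._fe = [np.ascontiguousarray(s.f_e, dtype=DTYPE) for s in subjects]
        self._ae_norm = [normalize_adjacency(rescale_pearson(s.a_e)) for s in subjects]
        self.history: list[LossReport] = []
        self.epoch_mae: list[float] = []
        self._step = 0

    # ------------------------------------------------------------ one batch
    def train_step(self, batch_indices: list[int]) -> LossReport:
        model = self.model
        model.train()
        cfg = self.config
        f_g_list = [model.generate(self.subjects[i].volume, self.subjects[i].embeddings)
                    for i in batch_indices]

        # (a) discriminator on L_d, generated series detached
        d_fake_det = [model.mtd(f_g.detach()) for f_g in f_g_list]
        d_real = [model.mtd(self._fe[i]) for i in batch_indices]
        l_d = loss_d(d_fake_det, d_real)
        model.zero_grad()
        l_d.backward()
        self.opt_disc.step()
        model.zero_grad()

        # (b) generator on L_g + L_rec (discriminator weights held fixed)
        d_fake = [model.mtd(f_g) for f_g in f_g_list]
        l_g = loss_g(d_fake)
        l_rec = _mean([loss_rec(f_g, self._fe[i], norm=cfg.rec_norm)
                       for f_g, i in zip(f_g_list, batch_indices)])
        mae = float(np.mean([np.abs(f_g.data - self._fe[i]).mean()
                             for f_g, i in zip(f_g_list, batch_indices)]))
        (l_g + l_rec).backward()
        self.opt_gen.step()
        model.zero_grad()

        # (c) connectivity learner + classifier with the generator frozen
        l_cls, l_reg = self._classifier_losses(
            batch_indices, [f_g.detach() for f_g in f_g_list])
        (l_cls + cfg.lambda_reg * l_reg).backward()
        self.opt_cls.step()
        model.zero_grad()

        self._step += 1
        report = LossReport(
            step=self._step,
            l_rec=l_rec.item(), l_g=l_g.item(), l_d=l_d.item(),
            l_cls=l_cls.item(), l_reg=l_reg.item(),
            l_all=(l_rec.item() + l_g.item() + l_d.item() + l_cls.item()
                   + cfg.lambda_reg * l_reg.item()),
            mae=mae)
        if not np.isfinite(report.l_all):
            raise NonFiniteLossError(f"non-finite loss at step {self._step}: {report}")
        self.history.append(report)
        return report

    def _classifier_losses(self, batch_indices: list[int],
                           f_g_detached: list[Tensor]) -> tuple[Tensor, Tensor]:
        model = self.model
        p_gen, p_emp, ys = [], [], []
        for f_g, i in zip(f_g_detached, batch_indices):
            subj = self.subjects[i]
            a_g = model.cl(f_g)
            p_gen.append(model.gcc(a_g, f_g))
            p_emp.append(model.gcc(self._ae_norm[i], self._fe[i], pre_normalized=True))
            ys.append(self._class_index[subj.label])
        return loss_cls(p_gen, p_emp, ys), loss_reg(model.cl.weight)

    # ----------------------------------------------------------------- fit
    def fit(self, epochs: int | None = None) -> pd.DataFrame:
        epochs = self.config.epochs if epochs is None else epochs
        n = len(self.subjects)
        bs = self.config.batch_size
        for _ in range(epochs):
            order = self.rng.permutation(n)
            epoch_rec = []
            for start in range(0, n, bs):
                batch = [int(i) for i in order[start:start + bs]]
                report = self.train_step(batch)
                epoch_rec.append(report.mae)
            self.epoch_mae.append(float(np.mean(epoch_rec)))
        if self.config.classifier_refine_steps:
            self.classifier_refine(self.config.classifier_refine_steps)
        return self.history_frame()

    def classifier_refine(self, steps: int) -> None:
        """Extra sub-step-(c) passes with cached generated series.

        The generator is converged and frozen at this point, so F_g per
        subject is computed once (eval mode) and the cheap connectivity +
        classifier updates iterate on the cache.
        """
        model = self.model
        model.eval()
        with no_grad():
            cache = [Tensor(np.asarray(
                model.generate(s.volume, s.embeddings).data, dtype=DTYPE))
                for s in self.subjects]
        model.train()
        n = len(self.subjects)
        bs = self.config.batch_size
        for _ in range(steps):
            batch = [int(i) for i in self.rng.choice(n, size=min(bs, n), replace=False)]
            l_cls, l_reg = self._classifier_losses(batch, [cache[i] for i in batch])
            model.zero_grad()
            (l_cls + self.config.lambda_reg * l_reg).backward()
            self.opt_cls.step()
            model.zero_grad()

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.history])
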