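"""Classification objectives: softmax, cross-entropy, and temperature-scaled
knowledge distillation.

The total training loss blends a hard-label term with a soft term that pulls
the student's temperature-softened class distribution toward a fixed
teacher's:  L = (1 - alpha) * L_ce + alpha * L_kd,  with
L_kd = tau^2 * KL(p_teacher^tau || p_student^tau) by default (the standard
distillation direction; the reversed direction is available via ``direction``).
All functions accept plain arrays and return autodiff tensors, so they can sit
at the top of a backward pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["KDConfig", "softmax", "cross_entropy", "kd_loss", "total_loss"]

_CLAMP = 1e-12  # probability floor before any log


@dataclass
class KDConfig:
    alpha: float = 0.7
    tau: float = 4.0
    direction: str = "teacher"  # "teacher": KL(t||s) targets; "student": KL(s||t)
    teacher: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.tau <= 0:
            raise ValueError("temperature must be positive")
        if self.direction not in ("teacher", "student"):
            raise ValueError("direction must be 'teacher' or 'student'")


def softmax(z) -> Tensor:
    """Row-wise softmax of logits (N, C), computed max-shifted."""
    z = z if isinstance(z, Tensor) else Tensor(z)
    if not np.all(np.isfinite(z.data)):
        raise FloatingPointError("non-finite logits")
    return ad.texp(ad.log_softmax(z, axis=-1))


def cross_entropy(probabilities, labels_onehot) -> Tensor:
    """Mean negative log-likelihood of one-hot labels under ``probabilities``.

    Probabilities are clamped at 1e-12 before the log so a zero probability at
    the true class yields a large finite loss instead of an infinity.
    """
    p = probabilities if isinstance(probabilities, Tensor) else Tensor(probabilities)
    y = np.asarray(labels_onehot, dtype=np.float64)
    if p.data.shape != y.shape:
        raise ValueError("probabilities and one-hot labels must share a shape")
    n = y.shape[0]
    return ad.tsum(ad.tlog(p + _CLAMP) * (-y)) * (1.0 / n)


def kd_loss(student_logits, teacher_logits, tau: float = 4.0,
            direction: str = "teacher") -> Tensor:
    """tau^2-scaled KL divergence between temperature-softened distributions.

    ``direction='teacher'`` (default) computes KL(p_t || p_s), the usual
    distillation target; ``'student'`` computes KL(p_s || p_t).
    Non-negative, zero iff the softened distributions coincide.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    zs = student_logits if isinstance(student_logits, Tensor) else Tensor(student_logits)
    zt = np.asarray(teacher_logits.data if isinstance(teacher_logits, Tensor)
                    else teacher_logits, dtype=np.float64)
    if not (np.all(np.isfinite(zs.data)) and np.all(np.isfinite(zt))):
        raise FloatingPointError("non-finite logits in kd_loss")
    if zs.data.shape != zt.shape:
        raise ValueError("student and teacher logits must share a shape")
    n = zs.data.shape[0]
    log_ps = ad.log_softmax(zs * (1.0 / tau), axis=-1)
    # teacher is a fixed reference: plain arrays
    zt_soft = zt / tau
    zt_soft = zt_soft - zt_soft.max(axis=-1, keepdims=True)
    log_pt = zt_soft - np.log(np.exp(zt_soft).sum(axis=-1, keepdims=True))
    pt = np.exp(log_pt)
    if direction == "teacher":
        # sum_t p_t * (log p_t - log p_s)
        kl = ad.tsum(Tensor(pt) * (Tensor(log_pt) - log_ps))
    elif direction == "student":
        ps = ad.texp(log_ps)
        kl = ad.tsum(ps * (log_ps - Tensor(log_pt)))
    else:
        raise ValueError("direction must be 'teacher' or 'student'")
    return kl * (tau * tau / n)


def total_loss(student_logits, teacher_logits, labels_onehot,
               cfg: KDConfig | None = None) -> Tensor:
    """Affine blend (1 - alpha) * cross-entropy + alpha * distillation loss.

    With no teacher logits (or alpha = 0) this reduces to plain cross-entropy.
    """
    cfg = cfg or KDConfig()
    ce = cross_entropy(softmax(student_logits), labels_onehot)
    if teacher_logits is None or cfg.alpha == 0.0:
        return ce
    kd = kd_loss(student_logits, teacher_logits, cfg.tau, cfg.direction)
    return ce * (1.0 - cfg.alpha) + kd * cfg.alpha
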