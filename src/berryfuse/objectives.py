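"""Loss functions: the heritable loss, the task loss, their total, and the
traditional orthogonal loss used as the conceptual baseline.

The heritable loss regularizes the three expert embeddings — the RGB
("father"), depth ("mother") and fused ("child") feature vectors:

* ``L_parent = cos_sim(father, mother)`` drives the two modality
  embeddings toward orthogonality (literal mode minimizes the signed
  cosine; absolute mode minimizes its magnitude),
* ``L_child = ReLU(|cos_sim(father, child) - cos_sim(mother, child)| - tau)``
  penalizes the child only when its similarity to the two parents is
  more asymmetric than the threshold tau; inside that band the loss is
  exactly zero with zero gradient, so the constraint is inactive.

``L_heritable = L_parent + L_child`` and
``L_total = L_task + lambda * L_heritable``.  The task loss is the mean
over samples of the summed squared per-task errors.

All functions accept either plain numpy arrays (returning floats) or
autodiff :class:`~berryfuse.autodiff.Tensor` batches of shape (n, d)
(returning scalar tensors averaged over the batch), so the same code
path serves training and analysis.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import Tensor

_EPS_NORM = 0.0  # zero vectors are an error, not smoothed over


@dataclasses.dataclass
class LossConfig:
    tau: float = 0.1
    lam: float = 0.1
    parent_mode: str = "literal"  # or "absolute"
    literal_middle_term: bool = False  # reproduce the unsquared second task term

    def __post_init__(self):
        if self.tau < 0 or self.lam < 0:
            raise ValueError("tau and lambda must be nonnegative")
        if self.parent_mode not in ("literal", "absolute"):
            raise ValueError(f"unknown parent_mode {self.parent_mode!r}")


@dataclasses.dataclass
class LossComponents:
    """Every scalar the training loop logs, on the standardized target scale."""

    l_parent: float
    l_father_child: float
    l_mother_child: float
    l_child: float
    l_heritable: float
    l_task: float
    l_total: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _as_batch(x) -> tuple[Tensor, bool]:
    """Promote to a (n, d) Tensor; remember whether input was a single vector."""
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
    single = t.ndim == 1
    if single:
        t = t.reshape(1, -1)
    return t, single


def _maybe_item(t: Tensor, want_float: bool):
    return t.item() if want_float else t


def cos_sim(u, v):
    """Cosine of the angle between u and v (batched over rows)."""
    ut, u_single = _as_batch(u)
    vt, v_single = _as_batch(v)
    un = (ut * ut).sum(axis=1)
    vn = (vt * vt).sum(axis=1)
    if np.any(un.data <= _EPS_NORM) or np.any(vn.data <= _EPS_NORM):
        raise ValueError("cosine similarity undefined for zero vectors")
    sim = (ut * vt).sum(axis=1) / (un.sqrt() * vn.sqrt())
    want_float = not isinstance(u, Tensor) and not isinstance(v, Tensor)
    out = sim.mean() if not (u_single and v_single) else sim.reshape(())
    return _maybe_item(out, want_float)


def _cos_rows(ut: Tensor, vt: Tensor) -> Tensor:
    un = (ut * ut).sum(axis=1)
    vn = (vt * vt).sum(axis=1)
    if np.any(un.data <= _EPS_NORM) or np.any(vn.data <= _EPS_NORM):
        raise ValueError("cosine similarity undefined for zero vectors")
    return (ut * vt).sum(axis=1) / (un.sqrt() * vn.sqrt())


def parent_loss(father, mother, parent_mode: str = "literal"):
    ft, _ = _as_batch(father)
    mt, _ = _as_batch(mother)
    sim = _cos_rows(ft, mt)
    if parent_mode == "absolute":
        sim = sim.abs()
    elif parent_mode != "literal":
        raise ValueError(f"unknown parent_mode {parent_mode!r}")
    out = sim.mean()
    return _maybe_item(out, not isinstance(father, Tensor))


def child_loss(father, mother, child, tau: float):
    """Thresholded asymmetry penalty: max(0, |cos(f,c) - cos(m,c)| - tau)."""
    ft, _ = _as_batch(father)
    mt, _ = _as_batch(mother)
    ct, _ = _as_batch(child)
    diff = (_cos_rows(ft, ct) - _cos_rows(mt, ct)).abs() - tau
    out = diff.relu().mean()
    return _maybe_item(out, not isinstance(father, Tensor))


def heritable_loss(embeddings, config: LossConfig):
    """L_parent + L_child averaged over the batch.

    ``embeddings`` is an object with father/mother/child attributes (see
    :class:`berryfuse.fusion_network.ExpertEmbeddings`).  Raises if the
    expert branches were ablated — with a single general network the three
    vectors coincide and the regularizer is meaningless.
    """
    if getattr(embeddings, "experts_ablated", False):
        raise ValueError("heritable loss relies on the presence of multiple experts; "
                         "it is unavailable when the expert branches are ablated")
    father, mother, child = embeddings.father, embeddings.mother, embeddings.child
    lp = parent_loss(father, mother, config.parent_mode)
    lc = child_loss(father, mother, child, config.tau)
    total = lp + lc
    ft, _ = _as_batch(father)
    mt, _ = _as_batch(mother)
    ct, _ = _as_batch(child)
    fc = _cos_rows(ft, ct).mean()
    mc = _cos_rows(mt, ct).mean()
    comps = LossComponents(
        l_parent=float(lp.item() if isinstance(lp, Tensor) else lp),
        l_father_child=fc.item(),
        l_mother_child=mc.item(),
        l_child=float(lc.item() if isinstance(lc, Tensor) else lc),
        l_heritable=float(total.item() if isinstance(total, Tensor) else total),
        l_task=np.nan, l_total=np.nan)
    return total, comps


def orthogonal_loss(embeddings):
    """Hard-constraint baseline: sum of squared cosines over the three pairs."""
    father, mother, child = embeddings.father, embeddings.mother, embeddings.child
    ft, _ = _as_batch(father)
    mt, _ = _as_batch(mother)
    ct, _ = _as_batch(child)
    out = ((_cos_rows(ft, mt) ** 2) + (_cos_rows(ft, ct) ** 2)
           + (_cos_rows(mt, ct) ** 2)).mean()
    return _maybe_item(out, not isinstance(father, Tensor))


def task_loss(predictions, labels, literal_middle_term: bool = False):
    """Mean over samples of the summed squared per-task errors.

    ``literal_middle_term`` leaves the second (uniformity) residual
    unsquared for audit of the printed form; the default squares all three.
    """
    pt, _ = _as_batch(predictions)
    lt, _ = _as_batch(labels)
    if pt.shape != lt.shape:
        raise ValueError(f"batch shape mismatch: {pt.shape} vs {lt.shape}")
    if pt.shape[0] == 0:
        raise ValueError("empty batch")
    err = pt - lt
    sq = err * err
    if literal_middle_term:
        per_sample = sq[:, 0] + err[:, 1] + sq[:, 2]
    else:
        per_sample = sq.sum(axis=1)
    out = per_sample.mean()
    return _maybe_item(out, not isinstance(predictions, Tensor))


def total_loss(l_task, l_heritable, lam: float):
    """L_task + lambda * L_heritable."""
    out = l_task + lam * l_heritable
    return out
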