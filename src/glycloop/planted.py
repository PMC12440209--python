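"""Synthetic planted-subgroup datasets (labelled fixtures, not CGM data).

These generators build meal-instance datasets with known ground-truth
subgroup structure directly in feature space. They exist to validate the
profiling and routing machinery: planted-cluster recovery, and the
qualitative claim that centroid-routed subgroup models beat a single global
baseline when behavioral subgroups genuinely differ.

Geometry: each event class (event / non-event) holds three subgroups whose
centers sit on distinct one-hot axes of the 12-dimensional clustering space,
``separation`` standard deviations apart; instances scatter around their
center with unit noise. For the classification benchmark an extra
discriminative offset of ``local_shift`` sd is added along a shared axis,
with a sign that alternates across subgroups: within a subgroup the event
and non-event populations are cleanly separated, but pooled globally the
offset's sign is uninformative, so a global model must learn the
subgroup x offset interaction while a routed local model sees a linear
boundary.
"""

from __future__ import annotations

import numpy as np

from .features import FeatureVector, MealInstance, N_FEATURES, FEATURE_NAMES

_HOUR = FEATURE_NAMES.index("meal_hour")
#: first clustering-space axis carrying the subgroup-specific class signal
_SIGNAL_AXIS = 6


def _vector_to_instance(v13: np.ndarray, label: int, subgroup: int,
                        pid: str) -> MealInstance:
    fv = FeatureVector(
        cgm_at_meal=float(v13[0]),
        hourly_means=tuple(float(x) for x in v13[1:7]),
        lbgi_6h=float(v13[7]),
        hbgi_6h=float(v13[8]),
        excursion_60=float(v13[9]),
        cho=float(v13[10]),
        meal_hour=int(v13[11]) % 24,
        mib=float(v13[12]),
    )
    inst = MealInstance(patient_id=pid, features=fv,
                        label_hypo=label, label_hyper=label)
    inst.planted_subgroup = subgroup  # ground truth, for recovery checks
    return inst


def make_planted_dataset(
    n_per_subgroup: int = 60,
    separation: float = 4.0,
    local_shift: float = 1.5,
    imbalance: int = 1,
    seed: int = 0,
) -> list[MealInstance]:
    """Planted 3-subgroups-per-class dataset (both labels coincide).

    Both classes of subgroup g share the blob center ``separation * e_g``
    (the subgroup is the pre-meal context, common to eventful and
    uneventful meals); the class signal of magnitude ``local_shift`` rides
    on a subgroup-specific axis with a sign that flips between event and
    non-event and alternates across subgroups, so pooled globally no single
    axis separates the classes without the subgroup interaction. Unit
    Gaussian noise on all 12 clustering dimensions. ``imbalance``
    multiplies the non-event subgroup sizes, emulating the rarity of
    adverse events.
    """
    rng = np.random.default_rng(seed)
    instances: list[MealInstance] = []
    cluster_dims = [i for i in range(N_FEATURES) if i != _HOUR]
    for label in (1, 0):
        for g in range(3):
            axis = cluster_dims[g]
            signal_axis = cluster_dims[_SIGNAL_AXIS + g]
            sign = 1.0 if g % 2 == 0 else -1.0
            n = n_per_subgroup * (imbalance if label == 0 else 1)
            for _ in range(n):
                v = np.zeros(N_FEATURES)
                noise = rng.normal(0.0, 1.0, size=len(cluster_dims))
                for d, nz in zip(cluster_dims, noise):
                    v[d] = nz
                v[axis] += separation
                v[signal_axis] += (
                    sign * local_shift * (1.0 if label == 1 else -1.0))
                v[_HOUR] = rng.integers(0, 24)
                instances.append(
                    _vector_to_instance(v, label, g, pid=f"planted{g}"))
    order = rng.permutation(len(instances))
    return [instances[i] for i in order]


def recovery_rate(instances: list[MealInstance], system: str = "S1") -> float:
    """Fraction of instances assigned to their planted subgroup.

    Cluster ids are matched to planted subgroups by the best label
    permutation within each event class, computed per class and pooled.
    """
    from itertools import permutations

    total, hits = 0, 0
    for label in (0, 1):
        subset = [i for i in instances
                  if (i.label_hypo if system == "S1" else i.label_hyper) == label]
        truth = np.array([i.planted_subgroup for i in subset])
        assigned = np.array([
            (i.cluster_id_s1 if system == "S1" else i.cluster_id_s2) % 3
            for i in subset])
        best = 0
        for perm in permutations(range(3)):
            mapped = np.array([perm[a] for a in assigned])
            best = max(best, int(np.sum(mapped == truth)))
        hits += best
        total += len(subset)
    return hits / total if total else 0.0


__all__ = ["make_planted_dataset", "recovery_rate"]
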