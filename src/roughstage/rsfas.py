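"""Rough set on fuzzy approximation space (RSFAS).

Real-valued attributes collected from patients are rarely exactly equal but
often *almost* equal; a crisp indiscernibility relation cannot see that.
The RSFAS construction replaces it with a fuzzy proximity relation

    L(x_i, x_j) = 1 − |v_i − v_j| / max(v_i, v_j)

(reflexive and symmetric by construction), thresholds it at a degree of
belongingness α and closes transitively, yielding α-equivalence classes of
"almost indiscernible" objects.  Rough lower/upper approximations are then
taken over those classes, and each attribute is quantized by ranking its
classes by mean value and assigning ordinal weights 1..k (Low/Medium/High
for k = 3, Very-Low..Very-High for k = 5).

Printed proximity tables round memberships to 2 decimals before comparing
with α; ``rounding_dp`` reproduces that, ``rounding_dp=None`` compares
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .infosys import AttributeSpec, InformationSystem

__all__ = [
    "membership",
    "proximity_matrix",
    "alpha_classes",
    "lower_upper",
    "quantize",
    "FuzzyProximityMatrix",
    "AlphaPartition",
    "RoughApproximation",
    "OrdinalSystem",
    "CategoricalAttributeSkip",
]

_EPS = 1e-12
#: float-safe slack when comparing rounded memberships with α
_CMP_TOL = 1e-9


class CategoricalAttributeSkip(ValueError):
    """Raised for attributes the proximity relation is not computed on."""


@dataclass(frozen=True)
class FuzzyProximityMatrix:
    """Symmetric per-attribute membership matrix with unit diagonal."""

    attribute: str
    objects: tuple[str, ...]
    values: np.ndarray
    rounding_dp: int | None = 2

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.objects)
        if v.shape != (n, n):
            raise ValueError("membership matrix shape does not match objects")
        if not np.allclose(v, v.T):
            raise ValueError("membership matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("membership matrix diagonal must be 1")
        if v.min() < -_CMP_TOL or v.max() > 1 + _CMP_TOL:
            raise ValueError("memberships must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.objects.index(pair[0])
        j = self.objects.index(pair[1])
        return float(self.values[i, j])


@dataclass(frozen=True)
class AlphaPartition:
    """α-equivalence classes of one attribute.

    ``classes`` are disjoint object-label tuples covering every object,
    ordered by the smallest member index; ``class_order`` ranks them by
    ascending mean attribute value (``class_order[r]`` is the index of the
    rank-(r+1) class) when the attribute values were supplied.
    """

    attribute: str
    alpha: float
    classes: tuple[tuple[str, ...], ...]
    class_order: tuple[int, ...] = ()

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def class_of(self, obj: str) -> int:
        for k, cls in enumerate(self.classes):
            if obj in cls:
                return k
        raise KeyError(f"object {obj!r} not in partition")


@dataclass(frozen=True)
class RoughApproximation:
    target: frozenset[str]
    lower: frozenset[str]
    upper: frozenset[str]

    @property
    def boundary(self) -> frozenset[str]:
        return self.upper - self.lower

    @property
    def is_alpha_rough(self) -> bool:
        return len(self.boundary) > 0


@dataclass
class OrdinalSystem:
    """Integer-weighted (1..k per attribute) version of an information system."""

    system: InformationSystem
    labels: dict[str, list[str]] = field(default_factory=dict)
    partitions: dict[str, AlphaPartition] = field(default_factory=dict)
    label_matrix: np.ndarray | None = None

    @property
    def values(self) -> np.ndarray:
        return self.system.values

    @property
    def object_ids(self) -> list[str]:
        return self.system.object_ids


def membership(v_i: float, v_j: float) -> float:
    """Degree of belongingness of two attribute values, in [0, 1].

    ``1 − |v_i − v_j| / max(v_i, v_j)`` for positive values; equal values
    (including both zero) give 1.  The formula is undefined for
    non-positive values, which do not occur in expression data; for those
    the absolute magnitudes replace the raw values in the denominator and
    the result is clipped to [0, 1].
    """
    if v_i == v_j:
        return 1.0
    m = max(v_i, v_j)
    if m <= 0.0:
        m = max(abs(v_i), abs(v_j), _EPS)
    return float(np.clip(1.0 - abs(v_i - v_j) / m, 0.0, 1.0))


def _membership_matrix(vals: np.ndarray) -> np.ndarray:
    vi = vals[:, None]
    vj = vals[None, :]
    denom = np.maximum(vi, vj)
    fallback = np.maximum(np.maximum(np.abs(vi), np.abs(vj)), _EPS)
    denom = np.where(denom > 0.0, denom, fallback)
    out = np.clip(1.0 - np.abs(vi - vj) / denom, 0.0, 1.0)
    np.fill_diagonal(out, 1.0)
    # exact equality → membership 1 regardless of sign
    out[vi == vj] = 1.0
    return out


def proximity_matrix(
    is_: InformationSystem,
    attribute: str,
    rounding_dp: int | None = 2,
) -> FuzzyProximityMatrix:
    """Pairwise membership matrix of one numeric attribute.

    Raises
    ------
    CategoricalAttributeSkip
        For categorical/decision/time/event attributes, on which the
        proximity relation is not computed.
    """
    spec = is_.spec(attribute)
    if spec.kind != "numeric":
        raise CategoricalAttributeSkip(
            f"attribute {attribute!r} is {spec.kind}; proximity not computed"
        )
    mat = _membership_matrix(is_.column(attribute))
    if rounding_dp is not None:
        mat = np.round(mat, rounding_dp)
        np.fill_diagonal(mat, 1.0)
    return FuzzyProximityMatrix(
        attribute=attribute,
        objects=tuple(is_.object_ids),
        values=mat,
        rounding_dp=rounding_dp,
    )


def alpha_classes(
    matrix: FuzzyProximityMatrix,
    alpha: float,
    attribute_values: np.ndarray | None = None,
) -> AlphaPartition:
    """Partition the objects into α-equivalence classes.

    Two objects are α-similar when their (rounded, if the matrix was built
    with rounding) membership is ≥ α; classes are the connected components
    of the α-similarity graph, i.e. the transitive closure of the relation.
    Classes are listed by their smallest member index.  When
    ``attribute_values`` is given, ``class_order`` ranks classes by
    ascending class mean (ties broken by smallest member index).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    adj = matrix.values >= alpha - _CMP_TOL
    n_comp, labels = connected_components(
        csr_matrix(adj), directed=False
    )
    classes: list[list[str]] = [[] for _ in range(n_comp)]
    for idx, lab in enumerate(labels):
        classes[lab].append(matrix.objects[idx])
    # deterministic: order classes by smallest member index
    order = sorted(
        range(n_comp), key=lambda c: matrix.objects.index(classes[c][0])
    )
    classes = [classes[c] for c in order]

    class_order: tuple[int, ...] = ()
    if attribute_values is not None:
        vals = np.asarray(attribute_values, dtype=float)
        pos = {o: i for i, o in enumerate(matrix.objects)}
        means = [float(np.mean([vals[pos[o]] for o in cls])) for cls in classes]
        class_order = tuple(
            sorted(range(len(classes)), key=lambda k: (means[k], k))
        )
    return AlphaPartition(
        attribute=matrix.attribute,
        alpha=float(alpha),
        classes=tuple(tuple(c) for c in classes),
        class_order=class_order,
    )


def lower_upper(
    partition: AlphaPartition, target: set[str] | frozenset[str]
) -> RoughApproximation:
    """Rough α-lower/upper approximation of a target object set.

    lower = union of classes wholly inside the target;
    upper = union of classes intersecting the target.

    Raises
    ------
    KeyError
        If the target contains an object not in the partition's universe.
    """
    universe = {o for cls in partition.classes for o in cls}
    target = frozenset(target)
    unknown = target - universe
    if unknown:
        raise KeyError(f"target contains unknown object(s): {sorted(unknown)}")
    lower: set[str] = set()
    upper: set[str] = set()
    for cls in partition.classes:
        cs = set(cls)
        if cs <= target:
            lower |= cs
        if cs & target:
            upper |= cs
    return RoughApproximation(
        target=target, lower=frozenset(lower), upper=frozenset(upper)
    )


_LABELS = {
    3: ["L", "M", "H"],
    5: ["VL", "L", "M", "H", "VH"],
}


def _rank_labels(k: int) -> list[str]:
    if k in _LABELS:
        return list(_LABELS[k])
    return [f"R{r}" for r in range(1, k + 1)]


def quantize(
    is_: InformationSystem,
    alpha: float | dict[str, float] = 0.97,
    rounding_dp: int | None = 2,
    max_classes_warn: int = 5,
) -> OrdinalSystem:
    """Quantize every numeric conditional attribute into ordinal weights.

    Per attribute: build the proximity matrix, cut at α (a scalar or a
    per-attribute mapping), rank the resulting classes by ascending class
    mean and assign weights 1..k (ascending value → ascending weight).
    k = 3 gets the Low/Medium/High vocabulary, k = 5 Very-Low..Very-High;
    any other count gets generic rank labels (a warning-worthy k >
    ``max_classes_warn`` still proceeds).  Categorical, decision, time and
    event attributes pass through unchanged.
    """
    import warnings

    values = is_.values.copy()
    labels: dict[str, list[str]] = {}
    partitions: dict[str, AlphaPartition] = {}
    label_matrix = np.empty(values.shape, dtype=object)

    for j, spec in enumerate(is_.attributes):
        if spec.kind != "numeric":
            label_matrix[:, j] = [str(v) for v in values[:, j]]
            continue
        a = alpha[spec.name] if isinstance(alpha, dict) else alpha
        mat = proximity_matrix(is_, spec.name, rounding_dp)
        part = alpha_classes(mat, a, attribute_values=is_.column(spec.name))
        partitions[spec.name] = part
        k = part.n_classes
        if k > max_classes_warn:
            warnings.warn(
                f"attribute {spec.name!r} yields {k} α-classes; "
                "using generic rank labels",
                stacklevel=2,
            )
        vocab = _rank_labels(k)
        labels[spec.name] = vocab
        # weight of class c = 1 + its rank position in class_order
        weight_of_class = {
            c: r + 1 for r, c in enumerate(part.class_order)
        }
        pos = {o: i for i, o in enumerate(is_.object_ids)}
        col = np.empty(is_.n_objects)
        for c, cls in enumerate(part.classes):
            w = weight_of_class[c]
            for o in cls:
                col[pos[o]] = w
                label_matrix[pos[o], j] = vocab[w - 1]
        values[:, j] = col

    ordinal = InformationSystem(
        object_ids=list(is_.object_ids),
        attributes=list(is_.attributes),
        values=values,
        decision_attribute=is_.decision_attribute,
        time_attribute=is_.time_attribute,
        event_attribute=is_.event_attribute,
    )
    return OrdinalSystem(
        system=ordinal,
        labels=labels,
        partitions=partitions,
        label_matrix=label_matrix,
    )
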