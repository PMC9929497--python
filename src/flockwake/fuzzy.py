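"""Piecewise-linear fuzzy machinery with 0-order Takagi–Sugeno inference.

A membership function is a continuous piecewise-linear map from a numeric
universe to [0, 1], defined by ordered anchor points and held constant
(plateau) outside the anchored range.  Rules are conjunctions of
(variable, term) clauses; the rule's firing strength is the t-norm of the
clause memberships (minimum by default, product optionally).  The crisp
output is the strength-weighted mean of the rules' constant consequents;
when no rule fires at all, a configurable fallback value is returned and a
``zero_fire`` flag raised so callers can tell the two apart.

OR and NOT connectives are provided as maximum and complement for
completeness; the in-wake rule base uses only AND.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, EvaluationError

__all__ = [
    "MembershipFunction",
    "LinguisticVariable",
    "FuzzyRule",
    "RuleBase",
    "f_and",
    "f_or",
    "f_not",
]


def f_and(*degrees, op: str = "min"):
    """Conjunction of membership degrees (t-norm)."""
    if op == "min":
        return np.minimum.reduce(list(map(np.asarray, degrees)))
    if op == "prod":
        return np.multiply.reduce(list(map(np.asarray, degrees)))
    raise ConfigError(f"unknown AND operator {op!r}")


def f_or(*degrees):
    """Disjunction of membership degrees (maximum s-norm)."""
    return np.maximum.reduce(list(map(np.asarray, degrees)))


def f_not(degree):
    """Standard fuzzy complement."""
    return 1.0 - np.asarray(degree)


@dataclass(frozen=True)
class MembershipFunction:
    """Continuous piecewise-linear membership function.

    Parameters
    ----------
    anchors:
        Ordered ``(x, m)`` pairs with strictly increasing ``x`` and
        ``m`` in [0, 1].  Evaluation linearly interpolates between them.
    left_plateau, right_plateau:
        Constant membership outside the anchored range.  Default to the
        first / last anchor membership, which keeps the function continuous.
    """

    anchors: tuple[tuple[float, float], ...]
    left_plateau: float | None = None
    right_plateau: float | None = None

    def __post_init__(self):
        if not self.anchors:
            raise ConfigError("membership function needs at least one anchor")
        xs = np.array([a[0] for a in self.anchors], dtype=float)
        ms = np.array([a[1] for a in self.anchors], dtype=float)
        if not np.isfinite(xs).all() or not np.isfinite(ms).all():
            raise ConfigError("non-finite anchor")
        if (np.diff(xs) <= 0).any():
            raise ConfigError("anchor inputs must be strictly increasing")
        if (ms < 0).any() or (ms > 1).any():
            raise ConfigError("anchor memberships must lie in [0, 1]")
        lp = ms[0] if self.left_plateau is None else float(self.left_plateau)
        rp = ms[-1] if self.right_plateau is None else float(self.right_plateau)
        if not (0 <= lp <= 1 and 0 <= rp <= 1):
            raise ConfigError("plateau memberships must lie in [0, 1]")
        object.__setattr__(self, "left_plateau", lp)
        object.__setattr__(self, "right_plateau", rp)
        object.__setattr__(self, "_xs", xs)
        object.__setattr__(self, "_ms", ms)

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if not np.isfinite(x).all():
            raise EvaluationError("membership evaluated at non-finite input")
        out = np.interp(x, self._xs, self._ms, left=self.left_plateau, right=self.right_plateau)
        return float(out) if out.ndim == 0 else out

    def complement(self) -> "MembershipFunction":
        """Pointwise complement 1 − m, again piecewise linear."""
        return MembershipFunction(
            anchors=tuple((x, 1.0 - m) for x, m in self.anchors),
            left_plateau=1.0 - self.left_plateau,
            right_plateau=1.0 - self.right_plateau,
        )

    def to_dict(self) -> dict:
        return {
            "anchors": [[x, m] for x, m in self.anchors],
            "left_plateau": self.left_plateau,
            "right_plateau": self.right_plateau,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MembershipFunction":
        return cls(
            anchors=tuple((float(x), float(m)) for x, m in d["anchors"]),
            left_plateau=d.get("left_plateau"),
            right_plateau=d.get("right_plateau"),
        )


@dataclass(frozen=True)
class LinguisticVariable:
    """A named input dimension with its fuzzy terms."""

    name: str
    terms: dict[str, MembershipFunction]
    universe: tuple[float, float] | None = None
    units: str = ""

    def __post_init__(self):
        if not self.terms:
            raise ConfigError(f"variable {self.name!r} has no terms")

    def membership(self, term: str, x):
        if term not in self.terms:
            raise EvaluationError(f"variable {self.name!r} has no term {term!r}")
        return self.terms[term](x)


@dataclass(frozen=True)
class FuzzyRule:
    """IF <conjunction of (variable IS term)> THEN <output IS value>."""

    antecedent: tuple[tuple[str, str], ...]
    consequent_label: str
    consequent_value: float

    def __post_init__(self):
        if not self.antecedent:
            raise ConfigError("rule needs at least one antecedent clause")
        if not np.isfinite(self.consequent_value):
            raise ConfigError("consequent value must be finite")


class RuleBase:
    """A 0-order Takagi–Sugeno system: variables, rules, crisp consequents."""

    def __init__(
        self,
        variables: list[LinguisticVariable],
        rules: list[FuzzyRule],
        zero_strength_output: float = 0.0,
        and_op: str = "min",
    ):
        self.variables = {v.name: v for v in variables}
        if len(self.variables) != len(variables):
            raise ConfigError("duplicate variable names")
        self.rules = list(rules)
        self.zero_strength_output = float(zero_strength_output)
        if and_op not in ("min", "prod"):
            raise ConfigError(f"unknown AND operator {and_op!r}")
        self.and_op = and_op
        for r in self.rules:
            for var, term in r.antecedent:
                if var not in self.variables:
                    raise ConfigError(f"rule references unknown variable {var!r}")
                if term not in self.variables[var].terms:
                    raise ConfigError(f"variable {var!r} has no term {term!r}")

    # -- evaluation ---------------------------------------------------------

    def rule_strength(self, rule: FuzzyRule, inputs: dict):
        """Firing strength of one rule (t-norm over clause memberships)."""
        degrees = []
        for var, term in rule.antecedent:
            if var not in inputs:
                raise EvaluationError(f"missing input for variable {var!r}")
            degrees.append(self.variables[var].membership(term, inputs[var]))
        return f_and(*degrees, op=self.and_op)

    def strengths(self, inputs: dict) -> np.ndarray:
        """Firing strengths of all rules; shape ``(n_rules,) + input shape``."""
        return np.array([self.rule_strength(r, inputs) for r in self.rules])

    def defuzzify(self, inputs: dict):
        """Crisp 0-order Takagi–Sugeno output.

        Returns ``(output, strengths, zero_fire)``.  The output is the
        strength-weighted mean of the consequent values; where the total
        strength is zero the fallback ``zero_strength_output`` is used and
        ``zero_fire`` is set.  Scalar inputs give scalars, array inputs give
        arrays (broadcast element-wise).
        """
        w = self.strengths(inputs)
        cons = np.array([r.consequent_value for r in self.rules])
        total = w.sum(axis=0)
        zero = total == 0.0
        safe = np.where(zero, 1.0, total)
        out = np.tensordot(cons, w, axes=(0, 0)) / safe
        out = np.where(zero, self.zero_strength_output, out)
        if np.ndim(total) == 0:
            return float(out), w, bool(zero)
        return out, w, zero

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "and_op": self.and_op,
            "zero_strength_output": self.zero_strength_output,
            "variables": [
                {
                    "name": v.name,
                    "units": v.units,
                    "universe": list(v.universe) if v.universe else None,
                    "terms": {t: mf.to_dict() for t, mf in v.terms.items()},
                }
                for v in self.variables.values()
            ],
            "rules": [
                {
                    "antecedent": [[var, term] for var, term in r.antecedent],
                    "consequent_label": r.consequent_label,
                    "consequent_value": r.consequent_value,
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RuleBase":
        variables = [
            LinguisticVariable(
                name=v["name"],
                units=v.get("units", ""),
                universe=tuple(v["universe"]) if v.get("universe") else None,
                terms={t: MembershipFunction.from_dict(m) for t, m in v["terms"].items()},
            )
            for v in d["variables"]
        ]
        rules = [
            FuzzyRule(
                antecedent=tuple((var, term) for var, term in r["antecedent"]),
                consequent_label=r["consequent_label"],
                consequent_value=float(r["consequent_value"]),
            )
            for r in d["rules"]
        ]
        return cls(
            variables,
            rules,
            zero_strength_output=float(d.get("zero_strength_output", 0.0)),
            and_op=d.get("and_op", "min"),
        )

    def to_json(self, path=None, **kw) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kw)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RuleBase":
        if hasattr(source, "read"):
            return cls.from_dict(json.load(source))
        text = str(source)
        if text.lstrip().startswith("{"):
            return cls.from_dict(json.loads(text))
        with open(text) as fh:
            return cls.from_dict(json.load(fh))
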