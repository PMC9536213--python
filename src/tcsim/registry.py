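"""Synapse-class registry: the 29 connection classes, their kinetic and
short-term-plasticity parameters, and the pre/post cell-type rules that assign
a class to every connection.

Each class carries a textual rule such as ``L5_TTPC:L5_TTPC`` or
``LBC-NBC_(bAC cAC bNAC dNAC):Excitatory``.  A rule side is a union of *atoms*,
each constraining some combination of layer, morphological type (m-type),
electrical type (e-type) and excitatory/inhibitory identity.  Lookup picks the
most specific matching class (count of constrained layer/m-type/e-type tokens
over both sides), breaking ties by the highest class index.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

# Electrical-type tokens as they appear in rules and in me-type names.  Rule
# tokens are matched as prefixes of the full e-type name (cAC -> cACint).
E_TYPE_TOKENS = (
    "cADpyr", "cACint", "cAC", "bAC", "cNAC", "bNAC", "dNAC",
    "cIR", "bIR", "cSTUT", "bSTUT", "dSTUT",
)

_LAYER_RE = re.compile(r"^L\d+$")


def _is_layer(tok: str) -> bool:
    return bool(_LAYER_RE.match(tok))


def _is_etype(tok: str) -> bool:
    return any(tok == t or t.startswith(tok) for t in E_TYPE_TOKENS) or tok in E_TYPE_TOKENS


def parse_me_type(name: str) -> tuple[str, str, str]:
    """Split ``L6_TPC_L4_cADpyr`` into (layer, m-type, e-type).

    m-types may themselves contain underscores (TPC_L4); the layer is the
    first token and the e-type the last.
    """
    parts = name.split("_")
    if len(parts) < 3 or not _is_layer(parts[0]) or not _is_etype(parts[-1]):
        raise ValueError(f"not a layer_mtype_etype name: {name!r}")
    return parts[0], "_".join(parts[1:-1]), parts[-1]


def _mtype_token_matches(token: str, m_type: str) -> bool:
    """A rule m-type token matches the exact m-type or a numbered/suffixed
    variant of it (TTPC -> TTPC1/TTPC2, TPC_L -> TPC_L4, NGC -> NGC-DA)."""
    if token == m_type:
        return True
    if m_type.startswith(token):
        rest = m_type[len(token):]
        return rest[0].isdigit() or rest[0] in "-_"
    return False


@dataclass(frozen=True)
class RuleAtom:
    """One conjunctive constraint on a single cell."""

    layer: str | None = None
    m_types: tuple[str, ...] = ()
    e_types: tuple[str, ...] = ()
    ei: bool | None = None  # True = excitatory, False = inhibitory

    @property
    def specificity(self) -> int:
        return int(self.layer is not None) + int(bool(self.m_types)) + int(bool(self.e_types))

    def matches(self, layer: str, m_type: str, e_type: str, excitatory: bool) -> bool:
        if self.layer is not None and self.layer != layer:
            return False
        if self.m_types and not any(_mtype_token_matches(t, m_type) for t in self.m_types):
            return False
        if self.e_types and not any(e_type == t or e_type.startswith(t) for t in self.e_types):
            return False
        if self.ei is not None and self.ei != excitatory:
            return False
        return True


def _split_top(text: str, sep: str) -> list[str]:
    """Split on ``sep`` outside any parenthesis/bracket nesting."""
    out, depth, cur = [], 0, []
    for ch in text:
        if ch in "([":
            depth += 1
        elif ch in ")]":
            depth -= 1
        if ch == sep and depth == 0:
            out.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    out.append("".join(cur))
    return [p for p in out if p]


def _parse_atom(spec: str) -> RuleAtom:
    """Parse one atom such as ``L6_TPC_L``, ``SBC_cAC``, ``L4_Excitatory``,
    ``LBC-NBC_(bAC cAC)``, ``(NBC-LBC)_(cAC cIR)`` or ``Excitatory``."""
    spec = spec.strip()
    norm = spec.lower()
    if norm in ("excitatory", "exc"):
        return RuleAtom(ei=True)
    if norm in ("inhibitory", "inh"):
        return RuleAtom(ei=False)

    layer: str | None = None
    m_types: list[str] = []
    e_types: list[str] = []
    ei: bool | None = None

    tokens = _split_top(spec, "_")

    def _plain_mtype(tok: str) -> bool:
        return (
            not tok.startswith("(")
            and not _is_layer(tok)
            and not _is_etype(tok)
            and tok.lower() not in ("excitatory", "exc", "inhibitory", "inh")
        )

    # Re-join underscore-containing m-types: a bare m-type-like token extends
    # the preceding m-type token (TPC + L -> TPC_L).
    merged: list[str] = []
    for tok in tokens:
        if merged and _plain_mtype(tok) and _plain_mtype(merged[-1]):
            merged[-1] = merged[-1] + "_" + tok
        else:
            merged.append(tok)

    for tok in merged:
        if tok.startswith("(") and tok.endswith(")"):
            members = re.split(r"[-\s]+", tok[1:-1].strip())
            members = [m for m in members if m]
            if all(_is_etype(m) for m in members):
                e_types.extend(members)
            else:
                m_types.extend(members)
        elif _is_layer(tok):
            layer = tok
        elif tok.lower() in ("excitatory", "exc"):
            ei = True
        elif tok.lower() in ("inhibitory", "inh"):
            ei = False
        elif _is_etype(tok):
            e_types.append(tok)
        else:
            m_types.extend(t for t in tok.split("-") if t)

    return RuleAtom(layer=layer, m_types=tuple(m_types), e_types=tuple(e_types), ei=ei)


def _parse_side(side: str) -> list[RuleAtom]:
    side = side.strip()
    if side.startswith("[") and side.endswith("]"):
        return [_parse_atom(p) for p in _split_top(side[1:-1], "-")]
    if side.startswith("(") and side.endswith(")") and " " in side:
        inner = side[1:-1].strip()
        # space-separated list of full atom specs, e.g. (BP_cAC DBC_cAC BTC_cAC)
        if all("_" in p for p in inner.split()):
            return [_parse_atom(p) for p in inner.split()]
    return [_parse_atom(side)]


@dataclass(frozen=True)
class PatternRule:
    """A parsed pre:post rule — a union of (pre-atoms, post-atoms) branches."""

    text: str
    branches: tuple[tuple[tuple[RuleAtom, ...], tuple[RuleAtom, ...]], ...]

    def match_specificity(self, pre: tuple, post: tuple) -> int | None:
        """Best specificity over matching branches, or None if no match."""
        best: int | None = None
        for pre_atoms, post_atoms in self.branches:
            pre_spec = max(
                (a.specificity for a in pre_atoms if a.matches(*pre)), default=None
            )
            if pre_spec is None:
                continue
            post_spec = max(
                (a.specificity for a in post_atoms if a.matches(*post)), default=None
            )
            if post_spec is None:
                continue
            total = pre_spec + post_spec
            best = total if best is None else max(best, total)
        return best


def parse_rule(text: str) -> PatternRule:
    """Parse a full rule string, handling top-level ``or`` alternation.

    An alternative lacking a colon (``SBC_bNAC or LBC-NBC_(...):Excitatory``)
    shares the post side of the following colon-bearing alternative.
    """
    # normalisation of printing quirks
    text = text.replace("Chc", "ChC")
    raw_alts = re.split(r"\s+or\s+", text)
    branches = []
    pending_pre: list[str] = []
    for alt in raw_alts:
        if ":" not in alt:
            pending_pre.append(alt)
            continue
        pre_s, post_s = alt.split(":", 1)
        post_atoms = tuple(_parse_side(post_s))
        pre_atoms = tuple(
            a for piece in pending_pre + [pre_s] for a in _parse_side(piece)
        )
        branches.append((pre_atoms, post_atoms))
        pending_pre = []
    if pending_pre:
        raise ValueError(f"dangling alternative without post side in {text!r}")
    return PatternRule(text=text, branches=tuple(branches))


@dataclass(frozen=True)
class SynapseClass:
    """One registry row: kinetics, short-term plasticity and the match rule."""

    index: int
    bbp_id: int
    s_type: str
    p_type: str
    g_syn: tuple[float, float]          # peak conductance, nS (mean, sd)
    tau_decay: tuple[float, float]      # ms (mean, sd)
    U: tuple[float, float]              # release probability (mean, sd)
    D: tuple[float, float]              # depression recovery, ms (mean, sd)
    F: tuple[float, float]              # facilitation recovery, ms (mean, sd)
    rule: PatternRule

    TAU_RISE: float = 0.2               # ms, common to all synapses

    @property
    def excitatory(self) -> bool:
        return self.s_type.startswith("E")

    @property
    def receptor(self) -> str:
        return "AMPA" if self.excitatory else "GABA_A"


@dataclass(frozen=True)
class SynapseParams:
    """Per-synapse sampled parameters."""

    g_syn: float
    tau_rise: float
    tau_decay: float
    U: float
    D: float
    F: float
    receptor: str


@dataclass(frozen=True)
class CalciumState:
    """Extracellular-calcium regime and its release-probability multipliers.

    In vitro corresponds to cao = 2.0 mM (multipliers 1); the in-vivo-like
    state lowers cao to 1.2 mM and scales U per dependence class.
    """

    cao: float = 2.0
    multipliers: dict = field(
        default_factory=lambda: {"steep": 1.0, "intermediate": 1.0, "shallow": 1.0}
    )

    @classmethod
    def in_vitro(cls) -> "CalciumState":
        return cls()

    @classmethod
    def in_vivo(cls, steep: float = 0.25, intermediate: float = 0.50,
                shallow: float = 0.75) -> "CalciumState":
        return cls(cao=1.2, multipliers={
            "steep": steep, "intermediate": intermediate, "shallow": shallow})


# m-types whose synapses onto them from pyramidal cells show steep (distal
# targeting) vs shallow (proximal/perisomatic targeting) calcium dependence.
DISTAL_TARGETING = ("DBC", "BTC", "MC", "BP")
PROXIMAL_TARGETING = ("LBC", "NBC", "SBC", "ChC")


def dependence_class(pre_excitatory: bool, post_m_type: str,
                     post_excitatory: bool) -> str:
    """Calcium-dependence class for a connection (steep / intermediate / shallow)."""
    if pre_excitatory and post_excitatory:
        return "steep"
    if pre_excitatory and any(
        _mtype_token_matches(t, post_m_type) for t in DISTAL_TARGETING
    ):
        return "steep"
    if pre_excitatory and any(
        _mtype_token_matches(t, post_m_type) for t in PROXIMAL_TARGETING
    ):
        return "shallow"
    return "intermediate"


def _data_path(name: str) -> Path:
    return Path(resources.files("tcsim").joinpath("data", name))


class SynapseRegistry:
    """The table of connection classes plus the packaged me-type roster."""

    def __init__(self, classes: list[SynapseClass], me_types: pd.DataFrame):
        self.classes = classes
        self.me_types = me_types
        self._ei = dict(zip(me_types["me_type"], me_types["excitatory"].astype(bool)))

    def __len__(self) -> int:
        return len(self.classes)

    def __getitem__(self, index: int) -> SynapseClass:
        return self.classes[index]

    def is_excitatory(self, me_type: str) -> bool:
        if me_type in self._ei:
            return self._ei[me_type]
        _, _, e_type = parse_me_type(me_type)
        return e_type.startswith("cAD")

    def match_class(self, pre_me_type: str, post_me_type: str) -> SynapseClass:
        """Resolve the connection class for an ordered me-type pair.

        The most specific matching rule wins; ties go to the highest index.
        The class's s-type letter must agree with the presynaptic identity
        (E* rules require an excitatory presynaptic cell, I* an inhibitory one).
        """
        pre = (*parse_me_type(pre_me_type), self.is_excitatory(pre_me_type))
        post = (*parse_me_type(post_me_type), self.is_excitatory(post_me_type))
        best: tuple[int, int] | None = None
        best_cls: SynapseClass | None = None
        for cls in self.classes:
            if cls.excitatory != pre[3]:
                continue
            spec = cls.rule.match_specificity(pre, post)
            if spec is None:
                continue
            key = (spec, cls.index)
            if best is None or key > best:
                best, best_cls = key, cls
        if best_cls is None:
            raise LookupError(
                f"no synapse class matches pair ({pre_me_type}, {post_me_type})")
        return best_cls

    def sample_params(self, cls: SynapseClass, rng: np.random.Generator,
                      size: int | None = None):
        """Draw per-synapse parameters from the class's mean/sd columns.

        Normal draws truncated below at 1% of the mean; U additionally
        truncated to (0, 1].
        """
        n = 1 if size is None else size

        def draw(mean, sd, upper=None):
            x = rng.normal(mean, sd, size=n)
            x = np.maximum(x, 0.01 * mean)
            if upper is not None:
                x = np.minimum(x, upper)
            return x

        g = draw(*cls.g_syn)
        tau = draw(*cls.tau_decay)
        tau = np.maximum(tau, cls.TAU_RISE * 1.5)  # dual-exponential validity
        U = draw(*cls.U, upper=1.0)
        D = draw(*cls.D)
        F = draw(*cls.F)
        if size is None:
            return SynapseParams(float(g[0]), cls.TAU_RISE, float(tau[0]),
                                 float(U[0]), float(D[0]), float(F[0]),
                                 cls.receptor)
        return {"g_syn": g, "tau_rise": np.full(n, cls.TAU_RISE),
                "tau_decay": tau, "U": U, "D": D, "F": F,
                "receptor": cls.receptor}

    def apply_calcium_scaling(self, params: SynapseParams, pre_me_type: str,
                              post_me_type: str, state: CalciumState) -> SynapseParams:
        """Scale U by the dependence-class multiplier; other fields unchanged."""
        dep = dependence_class(
            self.is_excitatory(pre_me_type),
            parse_me_type(post_me_type)[1],
            self.is_excitatory(post_me_type),
        )
        return replace(params, U=params.U * state.multipliers[dep])


def load_synapse_table(path: str | Path | None = None,
                       me_type_path: str | Path | None = None) -> SynapseRegistry:
    """Load the packaged registry (or a user-supplied TSV with equal columns)."""
    path = _data_path("synapse_classes.tsv") if path is None else Path(path)
    me_type_path = (
        _data_path("me_types.tsv") if me_type_path is None else Path(me_type_path)
    )
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"index", "bbp_id", "s_type", "p_type", "gsyn_mean", "gsyn_sd",
                "tau_decay_mean", "tau_decay_sd", "U_mean", "U_sd",
                "D_mean", "D_sd", "F_mean", "F_sd", "rule"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"registry file {path} missing columns {sorted(missing)}")
    classes = []
    for i, row in df.iterrows():
        try:
            cls = SynapseClass(
                index=int(row["index"]), bbp_id=int(row["bbp_id"]),
                s_type=str(row["s_type"]), p_type=str(row["p_type"]),
                g_syn=(float(row["gsyn_mean"]), float(row["gsyn_sd"])),
                tau_decay=(float(row["tau_decay_mean"]), float(row["tau_decay_sd"])),
                U=(float(row["U_mean"]), float(row["U_sd"])),
                D=(float(row["D_mean"]), float(row["D_sd"])),
                F=(float(row["F_mean"]), float(row["F_sd"])),
                rule=parse_rule(str(row["rule"])),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"bad registry row {i} in {path}: {exc}") from exc
        if not cls.g_syn[0] > 0 or not 0 < cls.U[0] < 1:
            raise ValueError(f"invalid means in registry row {i}")
        classes.append(cls)
    me = pd.read_csv(me_type_path, sep="\t")
    return SynapseRegistry(classes, me)
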