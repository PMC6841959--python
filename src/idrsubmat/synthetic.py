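"""Synthetic protein families with ordered/disordered architecture.

The generator emulates the two features of real disordered regions that the
matrix pipeline depends on: a biased residue composition (polar/charged-rich
in disordered segments, hydrophobic-rich in ordered ones) and a higher
substitution rate. Each family evolves on a star phylogeny: members derive
independently from one ancestor, each site substituting with probability
1 - exp(-rate); by default there are no indels, so the true alignment is
positional and every emitted annotation (disorder score 0.9/state 'C' in
disordered segments, 0.1/'H' in ordered ones) is exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .blocks import DisorderBin, assign_bin
from .io import (
    CANONICAL_ALPHABET,
    Alignment,
    FamilyTable,
    ProteinSequence,
    ResidueAnnotation,
    write_alignment,
    write_annotations,
    write_family_table,
    write_fasta,
)

_AA_INDEX = {a: i for i, a in enumerate(CANONICAL_ALPHABET)}

DISORDERED_SCORE = 0.9
ORDERED_SCORE = 0.1
DISORDERED_STATE = "C"
ORDERED_STATE = "H"


@dataclass(frozen=True)
class RegimeModel:
    """Residue composition and substitution rate of one structural regime.

    ``exchange_bias``, if given, maps a current residue to an unnormalized
    weight table over replacements; by default replacements are drawn from
    the regime composition restricted to differ from the current residue.
    """

    composition: np.ndarray  # length 20, canonical order, sums to 1
    subs_rate: float
    exchange_bias: Mapping[str, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        comp = np.asarray(self.composition, dtype=float)
        object.__setattr__(self, "composition", comp)
        if comp.shape != (len(CANONICAL_ALPHABET),):
            raise ValueError("composition must cover the 20 canonical residues")
        if abs(float(comp.sum()) - 1.0) > 1e-9:
            raise ValueError(f"composition sums to {comp.sum()}")
        if (comp < 0).any():
            raise ValueError("negative composition entry")
        if self.subs_rate < 0:
            raise ValueError("substitution rate must be >= 0")

    @property
    def p_substitution(self) -> float:
        """Per-site substitution probability along one branch."""
        return 1.0 - float(np.exp(-self.subs_rate))


def _composition_vector(mapping: Mapping[str, float]) -> np.ndarray:
    v = np.zeros(len(CANONICAL_ALPHABET))
    for aa, freq in mapping.items():
        v[_AA_INDEX[aa]] = freq
    return v


def default_regimes() -> dict[str, RegimeModel]:
    """The packaged disordered/ordered regimes (see data/regimes.yaml)."""
    text = resources.files("idrsubmat.data").joinpath("regimes.yaml").read_text()
    raw = yaml.safe_load(text)
    return {
        name: RegimeModel(
            composition=_composition_vector(entry["composition"]),
            subs_rate=float(entry["subs_rate"]),
        )
        for name, entry in raw.items()
    }


def scaled_regimes(
    factor: float, base: Mapping[str, RegimeModel] | None = None
) -> dict[str, RegimeModel]:
    """Regimes with every substitution rate multiplied by ``factor``.

    The default regimes describe a moderately diverged corpus (the kind a
    matrix is estimated from); test databases of remote homologs are the
    same regimes at a higher divergence factor.
    """
    if base is None:
        base = default_regimes()
    return {
        name: RegimeModel(
            composition=r.composition,
            subs_rate=r.subs_rate * factor,
            exchange_bias=r.exchange_bias,
        )
        for name, r in base.items()
    }


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for one family: size, length, segment architecture, seed."""

    n_members: int
    length: int
    architecture: tuple[tuple[str, int], ...]  # (regime name, segment length)
    seed: int

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise ValueError("a family needs at least 2 members")
        if sum(seg for _, seg in self.architecture) != self.length:
            raise ValueError("segment lengths must sum to the family length")


@dataclass(frozen=True)
class SyntheticFamily:
    family_id: str
    true_alignment: Alignment
    annotations: tuple[ResidueAnnotation, ...]
    spec: FamilySpec

    @property
    def members(self) -> tuple[ProteinSequence, ...]:
        return tuple(
            self.true_alignment.ungapped(i)
            for i in range(self.true_alignment.n_rows)
        )


def _segment_regimes(spec: FamilySpec) -> list[str]:
    """Regime name per site, expanded from the architecture."""
    out: list[str] = []
    for name, seg_len in spec.architecture:
        out.extend([name] * seg_len)
    return out


def sample_ancestor(
    spec: FamilySpec, regimes: Mapping[str, RegimeModel]
) -> ProteinSequence:
    """Draw the family ancestor segment by segment from regime compositions."""
    rng = np.random.default_rng(spec.seed)
    chunks: list[str] = []
    for name, seg_len in spec.architecture:
        if seg_len == 0:
            continue
        comp = regimes[name].composition
        draws = rng.choice(len(CANONICAL_ALPHABET), size=seg_len, p=comp)
        chunks.append("".join(CANONICAL_ALPHABET[k] for k in draws))
    return ProteinSequence(id="ancestor", residues="".join(chunks))


def _replacement_probs(regime: RegimeModel, current_idx: int) -> np.ndarray:
    if regime.exchange_bias is not None:
        cur = CANONICAL_ALPHABET[current_idx]
        bias = regime.exchange_bias.get(cur, {})
        w = np.array(
            [
                bias.get(aa, 1.0) * regime.composition[i]
                for i, aa in enumerate(CANONICAL_ALPHABET)
            ]
        )
    else:
        w = regime.composition.copy()
    w[current_idx] = 0.0
    total = w.sum()
    if total <= 0:
        w = np.ones(len(CANONICAL_ALPHABET))
        w[current_idx] = 0.0
        total = w.sum()
    return w / total


def evolve_family(
    spec: FamilySpec,
    regimes: Mapping[str, RegimeModel],
    family_id: str = "fam",
    indel_rate: float = 0.0,
    indel_extend: float = 0.5,
) -> SyntheticFamily:
    """Evolve ``n_members`` leaves from a fresh ancestor on a star phylogeny.

    Per member and site, a substitution happens with probability
    1 - exp(-subs_rate) of the site's regime; the replacement is drawn from
    the regime composition conditioned on differing from the current
    residue. With ``indel_rate`` > 0, disordered sites additionally suffer
    deletions (per-site probability ``indel_rate``) and spawn insertions of
    geometric length (success probability 1 - ``indel_extend``, mean
    1/(1-indel_extend)) drawn from the disordered composition — emulating
    the concentration of indels in disordered regions. The emitted
    alignment is the ground truth in either case; by default (no indels) it
    is strictly positional.
    """
    ancestor = sample_ancestor(spec, regimes)
    site_regimes = _segment_regimes(spec)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    anc_idx = np.array([_AA_INDEX[r] for r in ancestor.residues])
    member_sites: list[np.ndarray] = []
    kept: list[np.ndarray] = []
    insertions: list[dict[int, str]] = []
    for k in range(spec.n_members):
        member_idx = anc_idx.copy()
        u = rng.random(spec.length)
        for site, name in enumerate(site_regimes):
            regime = regimes[name]
            if u[site] < regime.p_substitution:
                probs = _replacement_probs(regime, member_idx[site])
                member_idx[site] = rng.choice(len(CANONICAL_ALPHABET), p=probs)
        member_sites.append(member_idx)
        keep = np.ones(spec.length, dtype=bool)
        ins: dict[int, str] = {}
        if indel_rate > 0:
            dis_sites = [
                i for i, name in enumerate(site_regimes) if name == "disordered"
            ]
            comp = None
            for name in site_regimes:
                if name == "disordered":
                    comp = regimes[name].composition
                    break
            for site in dis_sites:
                if rng.random() < indel_rate:
                    keep[site] = False
                if rng.random() < indel_rate:
                    length = int(rng.geometric(1.0 - indel_extend))
                    draws = rng.choice(
                        len(CANONICAL_ALPHABET), size=length, p=comp
                    )
                    ins[site] = "".join(CANONICAL_ALPHABET[j] for j in draws)
        kept.append(keep)
        insertions.append(ins)

    rows_chars: list[list[str]] = [[] for _ in range(spec.n_members)]
    col_regimes: list[list[str]] = [[] for _ in range(spec.n_members)]
    for site, name in enumerate(site_regimes):
        for k in range(spec.n_members):
            if kept[k][site]:
                rows_chars[k].append(CANONICAL_ALPHABET[member_sites[k][site]])
                col_regimes[k].append(name)
            else:
                rows_chars[k].append("-")
        for k in range(spec.n_members):
            inserted = insertions[k].get(site)
            if not inserted:
                continue
            for ch in inserted:
                for m in range(spec.n_members):
                    if m == k:
                        rows_chars[m].append(ch)
                        col_regimes[m].append("disordered")
                    else:
                        rows_chars[m].append("-")

    rows: list[tuple[str, str]] = []
    annotations: list[ResidueAnnotation] = []
    for k in range(spec.n_members):
        sid = f"{family_id}_m{k}"
        rows.append((sid, "".join(rows_chars[k])))
        scores = tuple(
            DISORDERED_SCORE if name == "disordered" else ORDERED_SCORE
            for name in col_regimes[k]
        )
        states = "".join(
            DISORDERED_STATE if name == "disordered" else ORDERED_STATE
            for name in col_regimes[k]
        )
        annotations.append(
            ResidueAnnotation(seq_id=sid, disorder_scores=scores, ss_states=states)
        )
    return SyntheticFamily(
        family_id=family_id,
        true_alignment=Alignment(rows=tuple(rows)),
        annotations=tuple(annotations),
        spec=spec,
    )


def stationary_pair_distribution(regime: RegimeModel) -> np.ndarray:
    """Closed-form leaf-pair residue distribution under the star model.

    For two leaves descending independently from an ancestor a ~ composition,
    P(x | a) = (1-m) [x=a] + m c_x / (1 - c_a) [x != a] with m the per-site
    substitution probability. Returns the symmetric ordered-pair matrix
    Q[x, y] (sums to 1 over all 400 ordered cells); every within-column leaf
    pair of an evolved family is distributed this way, whatever the column
    depth.
    """
    c = regime.composition
    m = regime.p_substitution
    n = len(c)
    trans = np.zeros((n, n))  # trans[a, x] = P(leaf residue x | ancestor a)
    for a in range(n):
        denom = 1.0 - c[a]
        for x in range(n):
            if x == a:
                trans[a, x] = 1.0 - m
            else:
                trans[a, x] = m * c[x] / denom if denom > 0 else m / (n - 1)
    return np.einsum("a,ax,ay->xy", c, trans, trans)


def write_fixture_set(
    families: Sequence[SyntheticFamily], out_dir: str | Path
) -> FamilyTable:
    """Emit the file tree every reader in :mod:`idrsubmat.io` consumes.

    Layout: ``aln/<family>.fasta`` (aligned), ``sequences.fasta`` (pool),
    ``scores/<seq>.tsv``, ``ss/<seq>.ss``, ``families.tsv``.
    """
    out = Path(out_dir)
    for sub in ("aln", "scores", "ss"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    membership: dict[str, str] = {}
    pool: list[ProteinSequence] = []
    for fam in families:
        write_alignment(fam.true_alignment, out / "aln" / f"{fam.family_id}.fasta")
        for i, ann in enumerate(fam.annotations):
            seq = fam.true_alignment.ungapped(i)
            write_annotations(
                ann,
                seq,
                out / "scores" / f"{seq.id}.tsv",
                out / "ss" / f"{seq.id}.ss",
            )
            membership[seq.id] = fam.family_id
            pool.append(seq)
    write_fasta(pool, out / "sequences.fasta")
    table = FamilyTable(membership=membership)
    write_family_table(table, out / "families.tsv")
    return table


@dataclass(frozen=True)
class Benchmark:
    families: tuple[SyntheticFamily, ...]
    table: FamilyTable
    bins: dict[str, DisorderBin]


def generate_benchmark(
    n_families: int,
    disorder_fraction: float,
    seed: int,
    n_members: int = 4,
    length: int = 240,
    regimes: Mapping[str, RegimeModel] | None = None,
) -> Benchmark:
    """A multi-family benchmark whose members share one disorder fraction.

    Each family gets an architecture of one ordered and one disordered
    segment sized so percent disorderedness equals ``disorder_fraction``;
    family seeds are spawned deterministically from ``seed``. The realized
    LD/MD/HD bin per family is recorded.
    """
    if n_families < 3:
        raise ValueError("need at least 3 families")
    if not (0.0 <= disorder_fraction <= 1.0):
        raise ValueError("disorder_fraction outside [0, 1]")
    if regimes is None:
        regimes = default_regimes()
    n_dis = round(disorder_fraction * length)
    architecture = tuple(
        seg
        for seg in (("ordered", length - n_dis), ("disordered", n_dis))
        if seg[1] > 0
    )
    child_seeds = np.random.SeedSequence(seed).generate_state(n_families)
    families: list[SyntheticFamily] = []
    bins: dict[str, DisorderBin] = {}
    for k in range(n_families):
        spec = FamilySpec(
            n_members=n_members,
            length=length,
            architecture=architecture,
            seed=int(child_seeds[k]) % (2**31),
        )
        fid = f"fam{k:03d}"
        fam = evolve_family(spec, regimes, family_id=fid)
        families.append(fam)
        bins[fid] = assign_bin(100.0 * n_dis / length)
    membership = {
        seq.id: fam.family_id for fam in families for seq in fam.members
    }
    return Benchmark(
        families=tuple(families),
        table=FamilyTable(membership=membership),
        bins=bins,
    )
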