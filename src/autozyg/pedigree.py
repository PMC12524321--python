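"""Pedigree ingestion, consistency checks, recursive tracing and the
numerator relationship matrix.

The pedigree-based inbreeding coefficient of an individual is the diagonal
of the additive (numerator) relationship matrix **A** minus one,
``F_PED(i) = A_ii - 1``.  **A** is built with the tabular method, treating
unknown parents as unrelated, non-inbred founders.  Because shallow
pedigrees systematically miss old autozygosity, F_PED is only reported for
individuals whose ancestry is completely recorded to a configurable number
of generations (default five).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = ""

_SEX_CODES = {
    "m": "male", "male": "male", "1": "male",
    "f": "female", "female": "female", "2": "female",
    "": "unknown", "0": "unknown", "u": "unknown", "unknown": "unknown",
}


@dataclass
class PedigreeRecord:
    """One animal: identifiers of its parents, sex and birth date.

    Unknown parents are encoded as the empty string; ``"0"`` in input files
    is normalised to unknown on read.
    """

    animal_id: str
    sire_id: str = UNKNOWN
    dam_id: str = UNKNOWN
    sex: str = "unknown"
    birth_date: _dt.date | None = None


@dataclass
class QCIssue:
    record_id: str
    code: str
    detail: str


@dataclass
class QCReport:
    """Log of every issue found and every modification made by validation."""

    issues: list[QCIssue] = field(default_factory=list)

    def add(self, record_id: str, code: str, detail: str) -> None:
        self.issues.append(QCIssue(record_id, code, detail))

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for iss in self.issues:
            out[iss.code] = out.get(iss.code, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i.record_id, i.code, i.detail) for i in self.issues],
            columns=["record_id", "issue", "detail"],
        )

    def __len__(self) -> int:
        return len(self.issues)


class Pedigree:
    """Topologically ordered collection of :class:`PedigreeRecord`.

    Every parent precedes its offspring in ``records``; referenced parents
    either resolve to a record or are explicitly unknown.
    """

    def __init__(self, records: list[PedigreeRecord]):
        self._index = {r.animal_id: r for r in records}
        if len(self._index) != len(records):
            raise ValueError("duplicate animal_id in pedigree")
        self.records = _topological_sort(records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self._index

    def __getitem__(self, animal_id: str) -> PedigreeRecord:
        return self._index[animal_id]

    @property
    def ids(self) -> list[str]:
        return [r.animal_id for r in self.records]

    def parents(self, animal_id: str) -> tuple[str, str]:
        r = self._index[animal_id]
        return r.sire_id, r.dam_id

    def founders(self) -> list[str]:
        return [r.animal_id for r in self.records
                if r.sire_id == UNKNOWN and r.dam_id == UNKNOWN]


@dataclass
class RelationshipMatrix:
    """Dense symmetric additive relationship matrix with its id order."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self._pos = {a: i for i, a in enumerate(self.ids)}

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self._pos[i], self._pos[j]])

    def diagonal(self) -> pd.Series:
        return pd.Series(np.diag(self.values), index=self.ids)

    def to_long_frame(self) -> pd.DataFrame:
        n = len(self.ids)
        ii, jj = np.triu_indices(n)
        return pd.DataFrame({
            "id_i": [self.ids[i] for i in ii],
            "id_j": [self.ids[j] for j in jj],
            "a": self.values[ii, jj],
        })


def _topological_sort(records: list[PedigreeRecord]) -> list[PedigreeRecord]:
    """Kahn's algorithm over the parent→offspring DAG; raises on cycles."""
    index = {r.animal_id: r for r in records}
    n_parents = {}
    children: dict[str, list[str]] = {a: [] for a in index}
    for r in records:
        known = [p for p in (r.sire_id, r.dam_id) if p in index]
        n_parents[r.animal_id] = len(known)
        for p in known:
            children[p].append(r.animal_id)
    queue = [a for a, k in n_parents.items() if k == 0]
    out: list[PedigreeRecord] = []
    while queue:
        a = queue.pop()
        out.append(index[a])
        for c in children[a]:
            n_parents[c] -= 1
            if n_parents[c] == 0:
                queue.append(c)
    if len(out) != len(records):
        cyclic = sorted(a for a, k in n_parents.items() if k > 0)
        raise ValueError(f"pedigree contains a cycle involving: {cyclic}")
    return out


def read_pedigree_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited pedigree file with columns id, sire, dam, sex,
    birth_date (ISO 8601); unknown parents may be empty or ``0``."""
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str,
                     keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def _parse_date(s) -> _dt.date | None:
    if s is None or (isinstance(s, float) and np.isnan(s)):
        return None
    s = str(s).strip()
    if not s or s == "0":
        return None
    try:
        return _dt.date.fromisoformat(s)
    except ValueError:
        return None


@dataclass
class PedigreeQCRules:
    """The consistency checks applied by :func:`validate_pedigree`.

    ``parent_age_min``/``parent_age_max``: a parent is expected to be
    between 2 and 30 years older than its offspring (configurable window;
    violations sever the parent link).  ``birth_year_min``/``max`` bound
    plausible birth dates.
    """

    parent_age_min: float = 2.0
    parent_age_max: float = 30.0
    birth_year_min: int = 1800
    birth_year_max: int = 2100


def validate_pedigree(
    rows: pd.DataFrame | list[dict],
    rules: PedigreeQCRules | None = None,
) -> tuple[Pedigree, QCReport]:
    """Apply the pedigree consistency checks and return a clean pedigree.

    Checks: duplicated ids, invalid sex codes, self-parenthood, identical
    sire and dam, parental-sex mismatch, implausible parental age, and
    unrealistic or missing birth dates.  Offending parent links are severed
    (set to unknown) and every action is logged; duplicate ids keep the
    first record.  Parental-sex mismatches are flagged but the link is kept,
    since the error may lie in the sex code rather than the link.

    Raises ``ValueError`` if a cycle survives link severing.
    """
    rules = rules or PedigreeQCRules()
    report = QCReport()
    if isinstance(rows, pd.DataFrame):
        rows = rows.to_dict("records")

    def norm_id(v) -> str:
        v = "" if v is None else str(v).strip()
        return UNKNOWN if v in ("", "0", "nan", "NA") else v

    records: list[PedigreeRecord] = []
    seen: dict[str, PedigreeRecord] = {}
    for row in rows:
        aid = norm_id(row.get("id") or row.get("animal_id"))
        if not aid:
            report.add("", "missing-id", "row without animal id dropped")
            continue
        sire = norm_id(row.get("sire") or row.get("sire_id"))
        dam = norm_id(row.get("dam") or row.get("dam_id"))
        raw_sex = str(row.get("sex", "")).strip().lower()
        if raw_sex in _SEX_CODES:
            sex = _SEX_CODES[raw_sex]
        else:
            sex = "unknown"
            report.add(aid, "invalid-sex", f"sex code {raw_sex!r} set unknown")
        bdate = _parse_date(row.get("birth_date") or row.get("birthdate"))
        raw_date = str(row.get("birth_date") or row.get("birthdate") or "").strip()
        if bdate is None:
            if raw_date and raw_date != "0":
                report.add(aid, "bad-birth-date",
                           f"unparseable birth date {raw_date!r}")
        elif not (rules.birth_year_min <= bdate.year <= rules.birth_year_max):
            report.add(aid, "bad-birth-date",
                       f"implausible birth year {bdate.year}")
            bdate = None
        rec = PedigreeRecord(aid, sire, dam, sex, bdate)
        if aid in seen:
            prev = seen[aid]
            same = (prev.sire_id == sire and prev.dam_id == dam)
            report.add(aid, "duplicate",
                       "identical duplicate dropped" if same
                       else "conflicting duplicate dropped, first kept")
            continue
        seen[aid] = rec
        records.append(rec)

    index = {r.animal_id: r for r in records}
    for r in records:
        if r.sire_id == r.animal_id:
            report.add(r.animal_id, "self-parent", "sire is the animal itself; severed")
            r.sire_id = UNKNOWN
        if r.dam_id == r.animal_id:
            report.add(r.animal_id, "self-parent", "dam is the animal itself; severed")
            r.dam_id = UNKNOWN
        if r.sire_id and r.sire_id == r.dam_id:
            report.add(r.animal_id, "sire-equals-dam",
                       f"sire and dam both {r.sire_id}; dam severed")
            r.dam_id = UNKNOWN
        for role, pid in (("sire", r.sire_id), ("dam", r.dam_id)):
            if not pid or pid not in index:
                continue
            parent = index[pid]
            expected = "male" if role == "sire" else "female"
            if parent.sex not in (expected, "unknown"):
                report.add(r.animal_id, "parental-sex-mismatch",
                           f"{role} {pid} recorded as {parent.sex}; link kept")
            if r.birth_date is not None and parent.birth_date is not None:
                age = (r.birth_date - parent.birth_date).days / 365.25
                if not (rules.parent_age_min <= age <= rules.parent_age_max):
                    report.add(r.animal_id, "implausible-parental-age",
                               f"{role} {pid} is {age:.1f} y older; severed")
                    if role == "sire":
                        r.sire_id = UNKNOWN
                    else:
                        r.dam_id = UNKNOWN

    _sever_cycles(records, report)
    return Pedigree(records), report


def _sever_cycles(records: list[PedigreeRecord], report: QCReport) -> None:
    """Break ancestry cycles by severing the newest edge in each cycle
    (newest by birth date, falling back to record order)."""
    order = {r.animal_id: i for i, r in enumerate(records)}

    def newness(r: PedigreeRecord):
        return (r.birth_date or _dt.date.min, order[r.animal_id])

    while True:
        try:
            _topological_sort(records)
            return
        except ValueError:
            index = {r.animal_id: r for r in records}
            cycle = _find_cycle(records)
            if cycle is None:  # pragma: no cover - sort failure implies cycle
                raise
            victim = max((index[a] for a in cycle), key=newness)
            report.add(victim.animal_id, "cycle",
                       f"cycle {sorted(cycle)}; parent links severed")
            victim.sire_id = UNKNOWN
            victim.dam_id = UNKNOWN


def _find_cycle(records: list[PedigreeRecord]) -> list[str] | None:
    index = {r.animal_id: r for r in records}
    color: dict[str, int] = {}
    stack_trace: list[str] = []

    def dfs(a: str) -> list[str] | None:
        color[a] = 1
        stack_trace.append(a)
        r = index[a]
        for p in (r.sire_id, r.dam_id):
            if p in index:
                if color.get(p, 0) == 1:
                    return stack_trace[stack_trace.index(p):]
                if color.get(p, 0) == 0:
                    found = dfs(p)
                    if found:
                        return found
        color[a] = 2
        stack_trace.pop()
        return None

    for a in index:
        if color.get(a, 0) == 0:
            found = dfs(a)
            if found:
                return found
    return None


def trace_ancestors(ped: Pedigree, animal_id: str, max_gen: int) -> Pedigree:
    """Sub-pedigree of ``animal_id`` and its ancestors within ``max_gen``
    generations; parents beyond the horizon become unknown."""
    return trace_ancestors_multi(ped, [animal_id], max_gen)


def trace_ancestors_multi(ped: Pedigree, animal_ids: list[str],
                          max_gen: int) -> Pedigree:
    """Union of the ``max_gen``-generation ancestries of several
    individuals; used to apply the generation horizon before building the
    relationship matrix for a genotyped cohort."""
    for aid in animal_ids:
        if aid not in ped:
            raise KeyError(f"unknown individual {aid!r}")
    if max_gen < 0:
        raise ValueError("max_gen must be >= 0")
    keep: dict[str, int] = {}  # id -> remaining generations budget

    frontier = [(aid, max_gen) for aid in animal_ids]
    while frontier:
        aid, budget = frontier.pop()
        if aid in keep and keep[aid] >= budget:
            continue
        keep[aid] = budget
        if budget == 0:
            continue
        for p in ped.parents(aid):
            if p in ped:
                frontier.append((p, budget - 1))

    records = []
    for aid in keep:
        src = ped[aid]
        # links among retained ancestors are kept; anything outside the
        # horizon was never added to `keep`, so its links vanish with it
        sire = src.sire_id if src.sire_id in keep else UNKNOWN
        dam = src.dam_id if src.dam_id in keep else UNKNOWN
        records.append(PedigreeRecord(aid, sire, dam, src.sex, src.birth_date))
    return Pedigree(records)


def generation_metrics(ped: Pedigree, animal_id: str) -> tuple[int, int]:
    """Return ``(depth, complete_generations)``.

    ``depth`` is the longest ancestral path; ``complete_generations`` is the
    largest g such that all 2**g ancestor slots at generation g are filled.
    """
    if animal_id not in ped:
        raise KeyError(f"unknown individual {animal_id!r}")
    depth_memo: dict[str, int] = {}
    complete_memo: dict[str, int] = {}

    def metrics(aid: str) -> tuple[int, int]:
        if aid in depth_memo:
            return depth_memo[aid], complete_memo[aid]
        sire, dam = ped.parents(aid)
        parents = [(p if p in ped else None) for p in (sire, dam)]
        if all(p is None for p in parents):
            d, c = 0, 0
        else:
            ds, cs = [], []
            for p in parents:
                if p is None:
                    ds.append(-1)
                    cs.append(-1)
                else:
                    pd_, pc = metrics(p)
                    ds.append(pd_)
                    cs.append(pc)
            d = 1 + max(ds)
            c = 1 + min(cs)
        depth_memo[aid] = d
        complete_memo[aid] = c
        return d, c

    return metrics(animal_id)


def build_a_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    ``A_ii = 1 + 0.5 A_sd`` and ``A_ij = 0.5 (A_j,sire(i) + A_j,dam(i))``
    for j preceding i; terms for unknown parents contribute zero.
    """
    ids = ped.ids
    pos = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for i, aid in enumerate(ids):
        sire, dam = ped.parents(aid)
        s = pos.get(sire, -1)
        d = pos.get(dam, -1)
        if s >= i or d >= i:
            raise ValueError("pedigree is not topologically ordered; "
                             "sort parents before offspring")
        asd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += A[:i, s]
            if d >= 0:
                row += A[:i, d]
            A[i, :i] = A[:i, i] = 0.5 * row
    return RelationshipMatrix(ids, A)


def f_ped(
    A: RelationshipMatrix,
    ped: Pedigree,
    ids: list[str] | None = None,
    min_complete_generations: int = 5,
) -> pd.Series:
    """Pedigree inbreeding ``F_PED(i) = A_ii - 1`` for individuals with at
    least ``min_complete_generations`` complete ancestral generations;
    others are reported as missing (NaN), never zero-filled."""
    ids = list(ids) if ids is not None else A.ids
    out = pd.Series(np.nan, index=ids, name="f_ped")
    for aid in ids:
        _, complete = generation_metrics(ped, aid)
        if complete >= min_complete_generations:
            out[aid] = A.loc(aid, aid) - 1.0
    return out
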