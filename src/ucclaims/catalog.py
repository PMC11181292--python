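"""Study drug catalog and scheduled-refill rules.

Each drug carries exactly one refill rule that defines its *next scheduled
prescription date* — the date the next refill is expected after a
prescription.  The rule is the anchor of the discontinuation algorithm in
:mod:`ucclaims.episodes`:

``fixed_weeks(k)``
    the next refill is expected ``k * 7`` days after the last prescription
    date, regardless of the dispensed amount (maintenance biologics given
    on a fixed schedule, e.g. ustekinumab every 12 weeks, infliximab and
    vedolizumab every 8 weeks);
``count_times_14``
    the dispensed count covers ``count * 14`` days (self-injected
    biologics dispensed as a number of syringes, e.g. adalimumab,
    golimumab);
``prescription_days``
    the dispensed quantity is a number of covered days (all oral drugs).

The shipped default catalog covers the drugs tabulated for ulcerative
colitis claims analyses: 5-ASA, oral and intravenous prednisolone, one
topical steroid, azathioprine, 6-mercaptopurine, the five biologics
(infliximab, adalimumab, golimumab, ustekinumab, vedolizumab) and the
small molecules (tofacitinib, tacrolimus, oral and intravenous
cyclosporine, each a distinct entry).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "DrugSpec",
    "DrugCatalog",
    "CatalogError",
    "next_scheduled_date",
    "refill_interval_days",
    "load_catalog",
    "default_catalog",
    "DRUG_CLASSES",
    "MTD_CLASSES",
    "ONSET_CLASSES",
]

DRUG_CLASSES = frozenset(
    {
        "5-ASA",
        "systemic_steroid",
        "topical_steroid",
        "immunomodulator",
        "biologic",
        "small_molecule",
    }
)
#: molecular targeting drugs = biologics plus small-molecule agents
MTD_CLASSES = frozenset({"biologic", "small_molecule"})
#: drug classes whose first new prescription proxies disease onset
ONSET_CLASSES = frozenset({"5-ASA", "systemic_steroid", "topical_steroid"})

ROUTES = frozenset({"po", "iv", "sc"})
RULES = frozenset({"fixed_weeks", "count_times_14", "prescription_days"})


class CatalogError(KeyError):
    """Unknown drug id or malformed catalog entry."""


@dataclass(frozen=True)
class DrugSpec:
    """One drug's class, route, and scheduled-refill rule."""

    drug_id: str
    display_name: str
    drug_class: str
    route: str
    rule: str
    rule_param: int | None = None

    def __post_init__(self) -> None:
        if self.drug_class not in DRUG_CLASSES:
            raise CatalogError(f"unknown drug class {self.drug_class!r} for {self.drug_id}")
        if self.route not in ROUTES:
            raise CatalogError(f"unknown route {self.route!r} for {self.drug_id}")
        if self.rule not in RULES:
            raise CatalogError(f"unknown refill rule {self.rule!r} for {self.drug_id}")
        if self.rule == "fixed_weeks":
            if self.rule_param is None or self.rule_param <= 0:
                raise CatalogError(
                    f"fixed_weeks rule for {self.drug_id} needs a positive week count"
                )


def refill_interval_days(spec: DrugSpec, dispensed: int) -> int:
    """Days until the next scheduled prescription date under ``spec``'s rule.

    ``dispensed`` is the dispensed count for ``count_times_14`` drugs and
    the number of covered days for ``prescription_days`` drugs; it is
    ignored by ``fixed_weeks`` rules.
    """
    if spec.rule == "fixed_weeks":
        return int(spec.rule_param) * 7  # weeks are exactly 7 calendar days
    if int(dispensed) < 1:
        raise ValueError(
            f"dispensed amount must be >= 1 for {spec.drug_id} ({spec.rule}); got {dispensed}"
        )
    if spec.rule == "count_times_14":
        return int(dispensed) * 14
    return int(dispensed)  # prescription_days


def next_scheduled_date(
    spec: DrugSpec, last_rx_date: pd.Timestamp, dispensed: int = 1
) -> pd.Timestamp:
    """Date the next refill is expected after a prescription."""
    last_rx_date = pd.Timestamp(last_rx_date)
    return last_rx_date + pd.Timedelta(days=refill_interval_days(spec, dispensed))


@dataclass
class DrugCatalog:
    """An id-unique collection of :class:`DrugSpec` entries."""

    entries: dict[str, DrugSpec] = field(default_factory=dict)

    @classmethod
    def from_specs(cls, specs: Iterable[DrugSpec]) -> "DrugCatalog":
        cat = cls()
        for spec in specs:
            if spec.drug_id in cat.entries:
                raise CatalogError(f"duplicate drug id {spec.drug_id!r}")
            cat.entries[spec.drug_id] = spec
        return cat

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self.entries

    def __iter__(self):
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, drug_id: str) -> DrugSpec:
        try:
            return self.entries[drug_id]
        except KeyError:
            raise CatalogError(f"drug id {drug_id!r} not in catalog") from None

    @property
    def class_index(self) -> Mapping[str, tuple[str, ...]]:
        """Mapping drug_class -> sorted drug ids of that class."""
        index: dict[str, list[str]] = {}
        for spec in self.entries.values():
            index.setdefault(spec.drug_class, []).append(spec.drug_id)
        return {cls_: tuple(sorted(ids)) for cls_, ids in index.items()}

    def ids_of_classes(self, classes: Iterable[str]) -> frozenset[str]:
        wanted = frozenset(classes)
        return frozenset(
            drug_id for drug_id, spec in self.entries.items() if spec.drug_class in wanted
        )

    @property
    def mtd_ids(self) -> frozenset[str]:
        return self.ids_of_classes(MTD_CLASSES)

    @property
    def onset_ids(self) -> frozenset[str]:
        return self.ids_of_classes(ONSET_CLASSES)

    def next_scheduled_date(
        self, drug_id: str, last_rx_date: pd.Timestamp, dispensed: int = 1
    ) -> pd.Timestamp:
        return next_scheduled_date(self.get(drug_id), last_rx_date, dispensed)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(
                ["drug_id", "display_name", "drug_class", "route", "rule", "rule_param"]
            )
            for spec in self.entries.values():
                writer.writerow(
                    [
                        spec.drug_id,
                        spec.display_name,
                        spec.drug_class,
                        spec.route,
                        spec.rule,
                        "" if spec.rule_param is None else spec.rule_param,
                    ]
                )


def _parse_rows(rows: Iterable[dict[str, str]], source: str) -> DrugCatalog:
    specs = []
    for row in rows:
        try:
            param_raw = (row.get("rule_param") or "").strip()
            specs.append(
                DrugSpec(
                    drug_id=row["drug_id"].strip(),
                    display_name=(row.get("display_name") or row["drug_id"]).strip(),
                    drug_class=row["drug_class"].strip(),
                    route=row["route"].strip(),
                    rule=row["rule"].strip(),
                    rule_param=int(param_raw) if param_raw else None,
                )
            )
        except (KeyError, ValueError) as exc:
            raise CatalogError(f"malformed catalog row in {source}: {row!r} ({exc})") from exc
    return DrugCatalog.from_specs(specs)


def load_catalog(path: str | Path) -> DrugCatalog:
    """Load a catalog from a tab-delimited config file.

    Columns: ``drug_id``, ``display_name``, ``drug_class``, ``route``,
    ``rule``, ``rule_param`` (``rule_param`` empty except for
    ``fixed_weeks``, where it is the week count).
    """
    with open(path, newline="") as fh:
        return _parse_rows(csv.DictReader(fh, delimiter="\t"), str(path))


def default_catalog() -> DrugCatalog:
    """The shipped study drug set."""
    ref = resources.files("ucclaims") / "data" / "default_catalog.tsv"
    with ref.open(newline="") as fh:
        return _parse_rows(csv.DictReader(fh, delimiter="\t"), "default_catalog.tsv")
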