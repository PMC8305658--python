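"""Co-segregation verdicts under incomplete penetrance.

Evaluates two variants carried by the same PDAC/breast-cancer family: a
SUFU promoter variant that tracks pancreatic disease (with healthy elderly
carriers exempted) and a FANCM missense variant that tracks breast cancer
instead.
"""

from pedseg import build_fixture_bundle, evaluate_cross_phenotype, evaluate_segregation
from pedseg.segregation import BREAST, PANCREATIC, PenetranceRule

bundle = build_fixture_bundle()
family = bundle.cohort.families["25-5-67"]
sufu = next(v for v in bundle.variants if v.gene == "SUFU")
fancm = next(v for v in bundle.variants if v.gene == "FANCM")

res = evaluate_segregation(family, sufu, PANCREATIC)
print(f"SUFU vs pancreatic disease: {res.verdict.value}")
print(f"  affected carriers {res.affected_carriers}/{res.affected_genotyped}, "
      f"healthy carriers exempted: "
      f"{[(e.individual_id, e.age_years) for e in res.exemptions]}")

cross = evaluate_cross_phenotype(
    family, fancm, [PANCREATIC, BREAST], PenetranceRule(max_affected_noncarriers=1)
)
for name, r in cross.items():
    print(f"FANCM vs {name}: {r.verdict.value} "
          f"(affected carriers {r.affected_carriers}/{r.affected_genotyped})")

# SUFU is carried by every pancreatic case -> a candidate despite three
# unaffected elderly carriers (incomplete penetrance).  FANCM is absent
# from every pancreatic case but carried by 4 of 5 breast-cancer cases:
# it fails pancreatic co-segregation yet may track breast cancer.
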