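"""External agreement between warehouse counts and an annual report.

agreement% = (1 - sum_p |N_ext,p - N_dwh,p| / sum_p N_dwh,p) * 100, with
the absolute discrepancy computed per product type and summed.
"""

from transfuqc import report_agreement
from transfuqc.warehouse import (
    BLOOD_BANK_TABLES, EXTERNAL_SCHEMA, Source, Warehouse, table_from_records,
)

products = []
for ptype, n in (("RBC", 98), ("PLT", 51)):
    for i in range(n):
        products.append({"product_id": f"{ptype}{i}", "product_type": ptype,
                         "product_code": "E0150", "donation_ids": ("N1",)})
bank = Source("blood_bank", "blood_bank", {
    "donors": table_from_records([], BLOOD_BANK_TABLES["donors"]),
    "donations": table_from_records([], BLOOD_BANK_TABLES["donations"]),
    "products": table_from_records(products, BLOOD_BANK_TABLES["products"]),
})
external = table_from_records(
    [{"year": 2010, "product_type": "RBC", "count": 100},
     {"year": 2010, "product_type": "PLT", "count": 50}],
    EXTERNAL_SCHEMA,
)
w = Warehouse(blood_bank=bank, hospitals={}, external_aggregates=external)

result = report_agreement(w)[0]
print(f"overall agreement: {result.numerator}/{result.denominator} = {result.percentage}%")
for ptype, cell in result.details["per_type"].items():
    print(f"  {ptype}: external {cell['external']} vs warehouse {cell['warehouse']}"
          f" -> {cell['agreement_pct']}%")
# Discrepancy |100-98| + |50-51| = 3 over 149 warehouse products: 97.99 %.
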