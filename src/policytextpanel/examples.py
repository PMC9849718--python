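"""Hand-crafted worked-example fixtures.

The three-document city corpus reproduces the canonical counting example: one
document with a collocation-qualified neutral keyword (10 occurrences), a plain
benefit-expansion keyword (4) and a cost-containment keyword (2), plus two
documents each carrying a cost-containment keyword 3 times.  Expected
prefecture-year totals: benefit_expansion = 14, cost_containment = 8.
"""

from __future__ import annotations

from .corpus import PolicyDocument


def worked_example_corpus() -> tuple[list[PolicyDocument], dict[str, int]]:
    """Three scheme documents for one prefecture-year, plus launch years.

    Token layout is chosen so every category keyword lands in the document's
    top-5 TF-IDF keywords under the raw tf * ln(N/df) scoring.
    """
    body1: list[str] = []
    for _ in range(10):
        body1 += ["increase", "reimbursement_rate"]
    body1 += ["supplementary_program"] * 4
    body1 += ["per_diem_payment"] * 2
    body1 += ["scheme_text", "announcement"]

    body23 = ["designated_facility_management"] * 3 + ["circular_text", "admin_note"]

    docs = [
        PolicyDocument(
            doc_id="gz-2012-1",
            prefecture_id="guangzhou",
            year=2012,
            title_tokens=("medical", "uebmi", "policy"),
            body_tokens=tuple(body1),
        ),
        PolicyDocument(
            doc_id="gz-2012-2",
            prefecture_id="guangzhou",
            year=2012,
            title_tokens=("medical", "uebmi", "notice"),
            body_tokens=tuple(body23),
        ),
        PolicyDocument(
            doc_id="gz-2012-3",
            prefecture_id="guangzhou",
            year=2012,
            title_tokens=("health", "uebmi", "notice"),
            body_tokens=tuple(body23),
        ),
    ]
    launch_years = {"guangzhou": 2012}
    return docs, launch_years
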