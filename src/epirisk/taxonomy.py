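"""POI functional taxonomy and reference survey means.

Six functional service categories split into 13 subcategories, following the
Chinese land-space planning use classification applied to map-provider POI
records. The subcategory counts are those of the Qingdao seven-district POI
inventory and serve as the default mixing proportions of the synthetic-city
generator; the Likert means are the published public-dependence survey column
and serve as the default survey targets.
"""

from __future__ import annotations

CATEGORIES: tuple[str, ...] = (
    "commercial",
    "residential",
    "public_service",
    "traffic",
    "green_space",
    "industrial",
)

#: subcategory -> parent category (13 subcategories over 6 categories)
SUBCATEGORY_PARENT: dict[str, str] = {
    "catering_service": "commercial",
    "shopping_service": "commercial",
    "accommodation_service": "commercial",
    "living_service": "commercial",
    "leisure_entertainment": "commercial",
    "business_residence": "residential",
    "medical_care": "public_service",
    "education_culture": "public_service",
    "government_agencies": "public_service",
    "athletic_sports": "public_service",
    "transportation_facilities": "traffic",
    "scenic_spots": "green_space",
    "companies": "industrial",
}

SUBCATEGORIES: tuple[str, ...] = tuple(SUBCATEGORY_PARENT)

#: published POI inventory counts per subcategory (Qingdao, 7 districts, 2022)
SUBCATEGORY_COUNTS: dict[str, int] = {
    "catering_service": 54_304,
    "shopping_service": 92_448,
    "accommodation_service": 12_364,
    "living_service": 68_669,
    "leisure_entertainment": 3_343,
    "business_residence": 9_250,
    "medical_care": 14_439,
    "education_culture": 17_474,
    "government_agencies": 15_507,
    "athletic_sports": 4_019,
    "transportation_facilities": 21_379,
    "scenic_spots": 2_007,
    "companies": 37_940,
}

TOTAL_POI_COUNT: int = sum(SUBCATEGORY_COUNTS.values())

#: published Likert-scale (1-5) mean dependence score per subcategory
SURVEY_MEANS: dict[str, float] = {
    "catering_service": 4.588,
    "shopping_service": 4.784,
    "accommodation_service": 3.814,
    "living_service": 4.270,
    "leisure_entertainment": 3.574,
    "business_residence": 3.191,
    "medical_care": 4.221,
    "education_culture": 4.368,
    "government_agencies": 4.093,
    "athletic_sports": 3.240,
    "transportation_facilities": 4.961,
    "scenic_spots": 4.064,
    "companies": 3.951,
}


def category_counts() -> dict[str, int]:
    """Aggregate subcategory counts to the six parent categories."""
    out = {c: 0 for c in CATEGORIES}
    for sub, n in SUBCATEGORY_COUNTS.items():
        out[SUBCATEGORY_PARENT[sub]] += n
    return out


def category_proportions() -> dict[str, float]:
    """Category shares of the total inventory (sum to 1 exactly)."""
    total = TOTAL_POI_COUNT
    return {c: n / total for c, n in category_counts().items()}


def subcategory_proportions() -> dict[str, float]:
    """Subcategory shares of the total inventory."""
    return {s: n / TOTAL_POI_COUNT for s, n in SUBCATEGORY_COUNTS.items()}
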