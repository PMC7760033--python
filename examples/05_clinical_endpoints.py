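"""Response labelling and survival endpoints on the published nivolumab table.

The second-radiological-assessment rule (responder iff therapy continued to a
third or later assessment) splits the 34-subject cohort 15/19 and separates
both time-to-treatment-failure and overall survival.
"""

from nmrfinger import compare_endpoint, group_counts, load_table1, median_endpoint
from nmrfinger.clinical import km_median_endpoint

records = load_table1()
n_r, n_nr = group_counts(records, "second_RA")
print(f"second-assessment rule: {n_r} responders / {n_nr} non-responders")

for endpoint in ("TTF", "OS"):
    med_r = median_endpoint(records, "second_RA", endpoint, "responder")
    med_nr = median_endpoint(records, "second_RA", endpoint, "non-responder")
    p = compare_endpoint(records, "second_RA", endpoint)
    print(f"{endpoint}: responders median {med_r:g} wk, "
          f"non-responders {med_nr:g} wk, p = {p:.2g}")

# Kaplan-Meier medians honour the censor flags instead of treating ongoing
# values as observed; they are the survival-analysis alternative.
print("KM OS medians:",
      km_median_endpoint(records, "second_RA", "OS", "responder"), "vs",
      km_median_endpoint(records, "second_RA", "OS", "non-responder"), "weeks")
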