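# Sensitivity-analysis extension: one additional demographics subdomain with
# four racial/ethnic composition features. Merged onto the default registry by
# build_sensitivity_registry(); demographics then has 8 equally weighted
# subdomains (each 1/32 of the overall index).
variant: race_ethnicity
subdomains:
  - subdomain_id: racial_ethnic_composition
    label: Racial and ethnic composition
    domain_id: demographics
features:
  - feature_id: pct_hispanic
    label: Hispanic/Latino of any race (%)
    subdomain_id: racial_ethnic_composition
    source: ACS
    direction: direct
    units: percent
  - feature_id: pct_black_nh
    label: Black non-Hispanic/Latino (%)
    subdomain_id: racial_ethnic_composition
    source: ACS
    direction: direct
    units: percent
  - feature_id: pct_asian_nh
    label: Asian non-Hispanic/Latino (%)
    subdomain_id: racial_ethnic_composition
    source: ACS
    direction: direct
    units: percent
  - feature_id: pct_other_nonwhite_nh
    label: Other non-White race non-Hispanic/Latino (%)
    subdomain_id: racial_ethnic_composition
    source: ACS
    direction: direct
    units: percent
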