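# Retrieve, per trial, the pair of arm-level endpoint results for two drugs.
# Placeholders {drug1}, {drug2}, {endpoint_id} are bound by the system;
# name comparison is case-insensitive after whitespace normalization.
PREFIX ctro: <https://w3id.org/diaet/ctro#>
SELECT ?trial ?drug1Name ?drug2Name ?res1 ?res2 ?endpoint1
WHERE {{
  ?trial a ctro:ClinicalTrial .
  ?trial ctro:hasArm ?arm1 .
  ?trial ctro:hasArm ?arm2 .
  ?arm1 ctro:hasDrugName ?drug1Name .
  ?arm2 ctro:hasDrugName ?drug2Name .
  ?arm1 ctro:hasEndpointResult ?res1 .
  ?arm2 ctro:hasEndpointResult ?res2 .
  ?res1 ctro:hasEndpointId ?endpoint1 .
  ?res2 ctro:hasEndpointId ?endpoint2 .
  FILTER(LCASE(STR(?drug1Name)) = "{drug1}")
  FILTER(LCASE(STR(?drug2Name)) = "{drug2}")
  FILTER(LCASE(STR(?endpoint1)) = "{endpoint_id}")
  FILTER(LCASE(STR(?endpoint2)) = "{endpoint_id}")
}}
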