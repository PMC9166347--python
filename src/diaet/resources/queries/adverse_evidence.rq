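# Retrieve, per trial, the pair of arm-level adverse-event counts for two drugs.
# Placeholders {drug1}, {drug2}, {event_id} are bound by the system.
PREFIX ctro: <https://w3id.org/diaet/ctro#>
SELECT ?trial ?drug1Name ?drug2Name ?ae1 ?ae2 ?event1
WHERE {{
  ?trial a ctro:ClinicalTrial .
  ?trial ctro:hasArm ?arm1 .
  ?trial ctro:hasArm ?arm2 .
  ?arm1 ctro:hasDrugName ?drug1Name .
  ?arm2 ctro:hasDrugName ?drug2Name .
  ?arm1 ctro:hasAdverseEvent ?ae1 .
  ?arm2 ctro:hasAdverseEvent ?ae2 .
  ?ae1 ctro:hasEventId ?event1 .
  ?ae2 ctro:hasEventId ?event2 .
  FILTER(LCASE(STR(?drug1Name)) = "{drug1}")
  FILTER(LCASE(STR(?drug2Name)) = "{drug2}")
  FILTER(LCASE(STR(?event1)) = "{event_id}")
  FILTER(LCASE(STR(?event2)) = "{event_id}")
}}
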