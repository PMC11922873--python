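raw,canonical
ORAL,oral
PO,oral
ORALLY,oral
BUCCAL,buccal
SUBLINGUAL,sublingual
TRANSDERMAL,transdermal
TOPICAL,topical
INTRAVENOUS,intravenous
INTRAVENOUS (NOT OTHERWISE SPECIFIED),intravenous
IV,intravenous
SUBCUTANEOUS,subcutaneous
INTRAMUSCULAR,intramuscular
INTRADUODENAL,intraduodenal
INTESTINAL INFUSION,intraduodenal
NASOGASTRIC TUBE,nasogastric
RECTAL,rectal
INHALATION,inhalation
RESPIRATORY (INHALATION),inhalation
OPHTHALMIC,ophthalmic
UNKNOWN,unknown
UNK,unknown
,unknown
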