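# Built-in term sets.  Schema: <key>: {name: <display name>, terms: [<lowercased
# exact preferred terms or generic drug names>]}.
#
# The diabetes term sets are documented approximations of the event lists used
# in published FAERS diabetes-signal analyses, whose exact lists are not
# freely redistributable; swap in your own file for production use
# (pvsignal --term-set path/to/file.yaml).

dm_core:
  name: DM-related adverse events (core)
  terms:
    - diabetes mellitus
    - diabetic ketoacidosis
    - diabetic coma

dm_extended:
  name: DM-related adverse events (extended, approximate)
  terms:
    - diabetes mellitus
    - diabetic ketoacidosis
    - diabetic coma
    - type 1 diabetes mellitus
    - type 2 diabetes mellitus
    - hyperglycaemia
    - blood glucose increased
    - glucose tolerance impaired
    - glycosylated haemoglobin increased
    - insulin resistance
    - diabetes mellitus inadequate control
    - ketoacidosis

vitamin_d:
  name: vitamin D analogues
  terms:
    - vitamin d
    - cholecalciferol
    - ergocalciferol
    - calcitriol
    - alfacalcidol
    - calcipotriol
    - paricalcitol
    - doxercalciferol
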