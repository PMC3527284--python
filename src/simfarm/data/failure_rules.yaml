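# Probable-cause rule table for failure classification.
# Rules are matched top-down against (phase, per-job log text); the first
# rule whose pattern (a substring) appears in an affected job's log wins.
# Edit freely — this table is data, not code.
rules:
  - phase: pre_execution
    pattern: "missing model"
    cause: "The job document lacks an embedded model; the task was split before the model was attached."
  - phase: pre_execution
    pattern: "missing required keys"
    cause: "The job document is malformed (missing task_type/output); regenerate the bundle from the task description."
  - phase: pre_execution
    pattern: "held"
    cause: "The job was held before execution, indicating a malformed job specification; inspect the job document and submit description."
  - phase: post_execution
    pattern: "steady state"
    cause: "The model failed to reach a steady state; extend the integration horizon or check the target mode."
  - phase: post_execution
    pattern: "non-finite"
    cause: "The simulation diverged (non-finite state); check rate constants and initial amounts."
  - phase: post_execution
    pattern: "unknown"
    cause: "The task fragment references a name the model does not define; check target expressions and parameter lists."
  - phase: post_execution
    pattern: "exit_status=1"
    cause: "The job executed but the task setup made it fail; inspect the job's error detail in its log."
fallback:
  pre_execution: "The job never executed; the submission was malformed."
  post_execution: "The job executed and exited with an error; the task setup is the likely problem."
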