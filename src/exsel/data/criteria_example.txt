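# Example diagnostic-criteria statements (DSM-5-style wording, paraphrased).
# Users should supply their own criteria file; this one keeps the pipeline
# and the examples runnable out of the box.
Depressed mood most of the day, nearly every day, such as feeling sad, empty, or hopeless.
Markedly diminished interest or pleasure in all, or almost all, activities most of the day.
Significant weight loss when not dieting, weight gain, or change in appetite nearly every day.
Insomnia or hypersomnia nearly every day.
Psychomotor agitation or retardation nearly every day, observable by others.
Fatigue or loss of energy nearly every day.
Feelings of worthlessness or excessive or inappropriate guilt nearly every day.
Diminished ability to think or concentrate, or indecisiveness, nearly every day.
Recurrent thoughts of death, recurrent suicidal ideation, or expressions of wanting to be hurt or broken.
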