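# Expert-curated cognitive-function screening keywords.
# A trailing hyphen marks a prefix stem (truncation search).
memory
agitat-
alter
alzheimer
attention
cognit-
confus-
decline
delirium
dementia
difficult
disorientation
drive
evaluat-
exam
forget-
function
impairment
loss
mental
mild
mmse
moca
montreal
mood
neuro-
orientation
psych-
question
recall
remember
score
sleep
speech
word
worse
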