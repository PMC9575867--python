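term,polarity
good,1
great,1
excellent,1
wonderful,1
amazing,1
hope,1
hopeful,1
proud,1
grateful,1
thankful,1
happy,1
joy,1
love,1
successful,1
resilient,1
congratulations,1
progress,1
improved,1
brave,1
inspiring,1
bad,-1
terrible,-1
awful,-1
horrible,-1
sad,-1
tragic,-1
tragedy,-1
angry,-1
afraid,-1
worried,-1
grief,-1
devastating,-1
worst,-1
painful,-1
shameful,-1
disastrous,-1
failing,-1
heartbreaking,-1
dreadful,-1
alarming,-1
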