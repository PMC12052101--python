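# Example synonym table: word<TAB>comma-separated pool members.
# Members that cannot be single corpus tokens (spaces, apostrophes,
# hyphens) are dropped on load.
measure	measure,step,quantity,amount,bill,measurement,standard,criterion,touchstone,meter,metre,cadence,bar
step	measure,step,quantity,amount,bill,measurement,standard,criterion,touchstone,meter,metre,cadence,bar
quantity	measure,step,quantity,amount,bill,measurement,standard,criterion,touchstone,meter,metre,cadence,bar
amount	measure,step,quantity,amount,bill,measurement,standard,criterion,touchstone,meter,metre,cadence,bar
bill	measure,step,quantity,amount,bill,measurement,standard,criterion,touchstone,meter,metre,cadence,bar
13	thirteen,13,XIII,baker's dozen,long dozen,xiii
thirteen	thirteen,13,XIII,baker's dozen,long dozen,xiii
xiii	thirteen,13,XIII,baker's dozen,long dozen,xiii
loquacious	loquacious,talkative,chatty,garrulous,voluble
obfuscate	obfuscate,confuse,obscure,blur
peregrinate	peregrinate,wander,roam
recondite	recondite,abstruse,deep
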