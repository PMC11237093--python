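term,generic_name,category,approval_year
semaglutide,semaglutide,weight_loss_active,2017
ozempic,semaglutide,weight_loss_active,2017
wegovy,semaglutide,weight_loss_active,2021
rybelsus,semaglutide,weight_loss_active,2019
tirzepatide,tirzepatide,weight_loss_active,2022
mounjaro,tirzepatide,weight_loss_active,2022
liraglutide,liraglutide,weight_loss_active,2010
saxenda,liraglutide,weight_loss_active,2014
dulaglutide,dulaglutide,diabetes_only,2014
trulicity,dulaglutide,diabetes_only,2014
exenatide,exenatide,diabetes_only,2005
bydureon,exenatide,diabetes_only,2012
byetta,exenatide,diabetes_only,2005
lixisenatide,lixisenatide,diabetes_only,2016
adlyxin,lixisenatide,diabetes_only,2016
retatrutide,retatrutide,investigational,
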